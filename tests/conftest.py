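import pytest

from lacriflow.clearance import ClearanceSchedule, two_stage_schedule
from lacriflow.geometry import load_table1
from lacriflow.hplc import fluconazole_curve
from lacriflow.synthesize import ExperimentDesign, generate_permeation_dataset


@pytest.fixture(scope="session")
def basal_schedule():
    """Single-regime basal turnover: 300 µL cleared at 11 %/min for 15 min."""
    return ClearanceSchedule.from_rates(300.0, [(0.11, 15.0)])


@pytest.fixture(scope="session")
def reflex_schedule():
    """Single-regime reflex tearing: 300 µL cleared at 16 %/min for 15 min."""
    return ClearanceSchedule.from_rates(300.0, [(0.16, 15.0)])


@pytest.fixture(scope="session")
def operating_schedule():
    """The standard two-stage run: 16 %/min for 2 min then 11 %/min for 13 min."""
    return two_stage_schedule()


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def curve():
    return fluconazole_curve()


@pytest.fixture(scope="session")
def default_records():
    return generate_permeation_dataset(ExperimentDesign(seed=1))
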