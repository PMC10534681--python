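"""Clearance mathematics: conversions, trajectories, AUC and recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lacriflow.clearance import (
    ClearanceRegime,
    ClearanceSchedule,
    auc_volume,
    beta_from_rate,
    discrete_volume,
    fit_beta,
    flow_for_rate,
    rate_for_flow,
    simulate_trajectory,
    two_stage_schedule,
)


class TestRateConversions:
    @pytest.mark.parametrize(
        "c, expected",
        [(0.11, 0.117), (0.16, 0.174), (0.0, 0.0), (0.5, 0.693)],
    )
    def test_coefficient_from_clearance_rate(self, c, expected):
        assert beta_from_rate(c) == pytest.approx(expected, abs=1e-12)

    def test_unrounded_coefficient_is_exact_log(self):
        assert beta_from_rate(0.11, rounded=False) == pytest.approx(
            -math.log(0.89), rel=1e-15
        )

    @pytest.mark.parametrize("c", [-0.01, 1.0, 1.5])
    def test_rate_outside_unit_interval_rejected(self, c):
        with pytest.raises(ValueError):
            beta_from_rate(c)

    @pytest.mark.parametrize(
        "c, v, flow", [(0.16, 300, 48.0), (0.11, 300, 33.0), (0.0, 300, 0.0)]
    )
    def test_pump_flow_for_clearance_rate(self, c, v, flow):
        assert flow_for_rate(c, v) == pytest.approx(flow, abs=1e-12)

    @pytest.mark.parametrize(
        "flow, v, c", [(1.1, 10, 0.11), (1.1, 7, 0.157), (48, 300, 0.16)]
    )
    def test_clearance_rate_for_pump_flow(self, flow, v, c):
        assert rate_for_flow(flow, v) == pytest.approx(c, abs=5e-4)

    def test_nonpositive_reference_volume_rejected(self):
        with pytest.raises(ValueError):
            flow_for_rate(0.1, 0.0)
        with pytest.raises(ValueError):
            rate_for_flow(1.0, -5.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        c=st.floats(min_value=0.0, max_value=0.999),
        v=st.floats(min_value=1e-3, max_value=1e6),
    )
    def test_flow_rate_round_trip(self, c, v):
        assert rate_for_flow(flow_for_rate(c, v), v) == pytest.approx(c, rel=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(c=st.floats(min_value=0.0, max_value=0.99))
    def test_coefficient_monotone_in_rate(self, c):
        assert beta_from_rate(c + 0.005, rounded=False) > beta_from_rate(
            c, rounded=False
        )


class TestDiscreteCompounding:
    @pytest.mark.parametrize(
        "k, percent", [(1, 89.0), (2, 79.21), (3, 70.4969)]
    )
    def test_minute_by_minute_basal_clearance(self, k, percent):
        v = discrete_volume(0.11, 300.0, k)
        assert 100.0 * v / 300.0 == pytest.approx(percent, abs=1e-10)

    def test_zero_steps_returns_initial_volume(self):
        assert discrete_volume(0.42, 123.0, 0) == 123.0

    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError):
            discrete_volume(0.11, 300.0, -1)

    def test_matches_continuous_model_at_whole_minutes(self):
        # (1-c)^k and exp(-beta k) are the same number when beta is unrounded
        sched = ClearanceSchedule.from_rates(300.0, [(0.11, 15.0)], rounded=False)
        for k in range(16):
            assert sched.volume_at(k) == pytest.approx(
                discrete_volume(0.11, 300.0, k), rel=1e-12
            )


class TestScheduleEvaluation:
    def test_initial_volume_at_time_zero(self, operating_schedule):
        assert operating_schedule.volume_at(0.0) == 300.0
        assert operating_schedule.percent_remaining(0.0) == 100.00

    def test_volume_at_regime_switch(self, operating_schedule):
        assert operating_schedule.volume_at(2.0) == pytest.approx(211.83, abs=0.2)

    def test_percent_after_full_two_stage_run(self, operating_schedule):
        assert operating_schedule.percent_remaining(15.0) == pytest.approx(
            15.43, abs=0.02
        )

    @pytest.mark.parametrize(
        "rate, expected", [(0.11, 17.29), (0.16, 7.35)]
    )
    def test_percent_after_15_min_single_regime(self, rate, expected):
        sched = ClearanceSchedule.from_rates(300.0, [(rate, 15.0)])
        assert sched.percent_remaining(15.0) == pytest.approx(expected, abs=0.02)

    def test_time_outside_horizon_rejected(self, operating_schedule):
        with pytest.raises(ValueError):
            operating_schedule.volume_at(-0.1)
        with pytest.raises(ValueError):
            operating_schedule.volume_at(15.1)

    def test_continuity_at_regime_switch(self, operating_schedule):
        for eps in (1e-3, 1e-6, 1e-9):
            gap = abs(
                operating_schedule.volume_at(2.0 - eps)
                - operating_schedule.volume_at(2.0 + eps)
            )
            assert gap < 300.0 * 0.2 * eps * 2  # bounded by max slope * width

    def test_semigroup_for_constant_coefficient(self):
        sched = ClearanceSchedule.from_rates(300.0, [(0.11, 20.0)])
        t1, t2 = 4.3, 7.9
        v_direct = sched.volume_at(t1 + t2)
        chained = ClearanceSchedule.from_rates(sched.volume_at(t1), [(0.11, 20.0)])
        assert chained.volume_at(t2) == pytest.approx(v_direct, rel=1e-12)

    def test_open_ended_final_regime(self):
        sched = ClearanceSchedule.from_string(300.0, "16:2,11:inf")
        assert math.isinf(sched.horizon)
        assert sched.volume_at(100.0) > 0

    def test_malformed_schedule_string_rejected(self):
        with pytest.raises(ValueError):
            ClearanceSchedule.from_string(300.0, "16-2")

    def test_unbounded_interior_regime_rejected(self):
        r_inf = ClearanceRegime.from_rate(0.16, math.inf)
        r = ClearanceRegime.from_rate(0.11, 5.0)
        with pytest.raises(ValueError):
            ClearanceSchedule(initial_volume=300.0, regimes=(r_inf, r))

    @settings(derandomize=True, max_examples=50)
    @given(
        rates=st.lists(
            st.floats(min_value=0.0, max_value=0.9), min_size=1, max_size=4
        ),
        t_frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_volume_positive_and_bounded_by_initial(self, rates, t_frac):
        sched = ClearanceSchedule.from_rates(300.0, [(r, 5.0) for r in rates])
        t = t_frac * sched.horizon
        v = sched.volume_at(t)
        assert 0 < v <= 300.0


class TestTrajectorySimulation:
    def test_zero_clearance_keeps_volume_constant(self):
        sched = ClearanceSchedule.from_rates(250.0, [(0.0, 10.0)])
        traj = simulate_trajectory(sched, dt=0.5)
        assert np.all(traj.volumes == 250.0)
        assert np.all(traj.drained == 0.0)

    def test_fine_grid_matches_closed_form_endpoint(self, operating_schedule):
        traj = simulate_trajectory(operating_schedule, dt=0.001)
        closed = operating_schedule.volume_at(15.0)
        assert traj.volumes[-1] == pytest.approx(closed, rel=1e-3)

    def test_mass_balance_and_monotone_decay(self, operating_schedule):
        traj = simulate_trajectory(operating_schedule, dt=0.05)
        np.testing.assert_allclose(traj.volumes + traj.drained, 300.0, rtol=1e-9)
        assert np.all(np.diff(traj.volumes) <= 0)

    def test_nonpositive_grid_step_rejected(self, operating_schedule):
        with pytest.raises(ValueError):
            simulate_trajectory(operating_schedule, dt=0.0)

    def test_csv_round_trip(self, operating_schedule, tmp_path):
        import pandas as pd

        path = tmp_path / "traj.csv"
        simulate_trajectory(operating_schedule, dt=0.5).to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["time_min", "volume_uL", "percent", "drained_uL"]
        assert frame.volume_uL.iloc[0] == 300.0

    def test_euler_compounding_converges_to_continuous(self):
        # independent oracle: apply the clearance flow stepwise, V <- V(1 - beta*h);
        # the error against the closed form must shrink monotonically with h
        beta = beta_from_rate(0.11)
        target = 300.0 * math.exp(-beta * 15.0)
        errors = []
        for h in (1.0, 0.1, 0.01):
            v = 300.0
            for _ in range(int(round(15.0 / h))):
                v *= 1.0 - beta * h
            errors.append(abs(v - target))
        assert errors[0] > errors[1] > errors[2]
        # first-order scheme: error shrinks roughly linearly in h
        assert errors[2] < errors[1] / 5 < errors[0] / 25


class TestExposureAuc:
    def test_no_clearance_gives_rectangle(self):
        sched = ClearanceSchedule.from_rates(300.0, [(0.0, 15.0)])
        assert auc_volume(sched, 15.0) == pytest.approx(4500.0, rel=1e-12)

    def test_single_regime_matches_trapezoid_oracle(self, basal_schedule):
        closed = auc_volume(basal_schedule, 15.0)
        assert closed == pytest.approx(2120.8, abs=0.1)
        t = np.linspace(0.0, 15.0, 150_001)
        v = np.array([basal_schedule.volume_at(x) for x in t])
        assert closed == pytest.approx(np.trapezoid(v, t), rel=1e-8)

    def test_two_stage_matches_trapezoid_oracle(self, operating_schedule):
        t = np.linspace(0.0, 15.0, 150_001)
        v = np.array([operating_schedule.volume_at(x) for x in t])
        assert auc_volume(operating_schedule, 15.0) == pytest.approx(
            np.trapezoid(v, t), rel=1e-8
        )

    def test_zero_horizon_and_negative_endpoint(self, basal_schedule):
        assert auc_volume(basal_schedule, 0.0) == 0.0
        with pytest.raises(ValueError):
            auc_volume(basal_schedule, -1.0)


class TestCoefficientRecovery:
    def test_noiseless_recovery_to_machine_precision(self):
        t = np.linspace(0.0, 15.0, 31)
        v = 300.0 * np.exp(-0.117 * t)
        assert fit_beta(t, v) == pytest.approx(0.117, rel=1e-6)

    def test_constant_volume_gives_zero_coefficient(self):
        assert fit_beta([0, 1, 2, 3], [300.0] * 4) == pytest.approx(0.0, abs=1e-15)

    def test_median_error_under_multiplicative_noise(self):
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            t = np.linspace(0.0, 15.0, 100)
            v = 300.0 * np.exp(-0.117 * t) * (1 + 0.01 * rng.standard_normal(100))
            errors.append(abs(fit_beta(t, v) - 0.117) / 0.117)
        assert np.median(errors) < 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_beta([0, 1], [300, 200])
        with pytest.raises(ValueError):
            fit_beta([0, 1, 2], [300, 0.0, 100])


def test_two_stage_schedule_records_pump_flows():
    sched = two_stage_schedule()
    assert [r.flow for r in sched.regimes] == [48.0, 33.0]
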