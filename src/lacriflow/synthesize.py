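"""Seeded generator of synthetic corneal-penetration experiments.

Stands in for the ex vivo porcine-eye assays: seven fluconazole
formulations (an aqueous solution, three poloxamer 407 gels at 14/16/20 %
w/w, and three 16 % poloxamer gels with 0.5/1.0/1.25 % chitosan) are each
"run" in two arms — a static Franz-cell protocol in quintuplicate and the
dynamic simulated-tear-flow protocol in quadruplicate.  Replicate amounts
(µg/cm² of cornea) are drawn from a lognormal with a configured true mean
and coefficient of variation, so every draw is strictly positive and fully
reproducible from the seed.

The default means encode the qualitative pattern the two models resolve:

* static arm: all formulations deposit similar amounts (~3 µg/cm²) — the
  static protocol cannot separate them;
* dynamic arm: mucoadhesive chitosan gels resist washout (~1.5 µg/cm²)
  while poloxamer-only gels and the plain solution are cleared (~0.5
  µg/cm²), independent of poloxamer percentage;
* consequently the static/dynamic ratio is ≈6x for poloxamer-only
  formulations (an overestimation of more than five-fold) and ≈2x for
  chitosan gels.

All means, the CV, replicate counts and the seed are overridable via
:class:`ExperimentDesign` or a YAML config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_FORMULATIONS",
    "ExperimentDesign",
    "FormulationSpec",
    "generate_permeation_dataset",
    "write_records",
]

RECORD_COLUMNS = ["formulation", "model", "replicate", "amount_ug_per_cm2", "seed"]


@dataclass(frozen=True)
class FormulationSpec:
    """True penetration means for one formulation in both arms.

    ``mean_static`` / ``mean_dynamic`` are true mean penetrated amounts in
    µg/cm²; ``cv`` is the lognormal coefficient of variation shared by both
    arms.
    """

    name: str
    poloxamer_pct: float
    chitosan_pct: float
    mean_static: float
    mean_dynamic: float
    cv: float = 0.25

    def __post_init__(self) -> None:
        if self.mean_static <= 0 or self.mean_dynamic <= 0:
            raise ValueError("true means must be positive")
        if self.cv <= 0:
            raise ValueError("coefficient of variation must be positive")
        if self.poloxamer_pct < 0 or self.chitosan_pct < 0:
            raise ValueError("excipient percentages must be non-negative")

    @property
    def is_chitosan(self) -> bool:
        return self.chitosan_pct > 0

    @property
    def is_poloxamer_only(self) -> bool:
        return self.poloxamer_pct > 0 and self.chitosan_pct == 0


DEFAULT_FORMULATIONS: tuple[FormulationSpec, ...] = (
    FormulationSpec("SOL", 0.0, 0.0, 3.0, 0.5),
    FormulationSpec("PLX14", 14.0, 0.0, 3.0, 0.5),
    FormulationSpec("PLX16", 16.0, 0.0, 3.0, 0.5),
    FormulationSpec("PLX20", 20.0, 0.0, 3.0, 0.5),
    FormulationSpec("PLX16C050", 16.0, 0.5, 3.0, 1.5),
    FormulationSpec("PLX16C100", 16.0, 1.0, 3.0, 1.5),
    FormulationSpec("PLX16C125", 16.0, 1.25, 3.0, 1.5),
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Replicate structure and noise seed of one synthetic experiment."""

    seed: int
    replicates_static: int = 5
    replicates_dynamic: int = 4
    formulations: tuple[FormulationSpec, ...] = DEFAULT_FORMULATIONS

    def __post_init__(self) -> None:
        if self.replicates_static < 1 or self.replicates_dynamic < 1:
            raise ValueError("replicate counts must be at least 1")
        names = [f.name for f in self.formulations]
        if len(names) != len(set(names)):
            raise ValueError("duplicate formulation names in design")
        if not self.formulations:
            raise ValueError("design needs at least one formulation")
        object.__setattr__(self, "formulations", tuple(self.formulations))

    @classmethod
    def from_yaml(cls, path: str | Path, *, seed: int | None = None) -> "ExperimentDesign":
        """Load a design from YAML; an explicit ``seed`` overrides the file's."""
        raw = yaml.safe_load(Path(path).read_text())
        forms = tuple(
            FormulationSpec(
                name=f["name"],
                poloxamer_pct=f.get("poloxamer_pct", 0.0),
                chitosan_pct=f.get("chitosan_pct", 0.0),
                mean_static=f["mean_static"],
                mean_dynamic=f["mean_dynamic"],
                cv=f.get("cv", raw.get("cv", 0.25)),
            )
            for f in raw["formulations"]
        ) if "formulations" in raw else DEFAULT_FORMULATIONS
        return cls(
            seed=seed if seed is not None else raw.get("seed", 0),
            replicates_static=raw.get("replicates_static", 5),
            replicates_dynamic=raw.get("replicates_dynamic", 4),
            formulations=forms,
        )

    def with_seed(self, seed: int) -> "ExperimentDesign":
        return replace(self, seed=seed)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of ln X for a lognormal with the given mean and CV."""
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_permeation_dataset(design: ExperimentDesign) -> pd.DataFrame:
    """Draw one full two-arm experiment as a tidy record table.

    Columns: formulation, model ("static"/"dynamic"), replicate (1-based),
    amount_ug_per_cm2, seed.  Deterministic given the design.
    """
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    for spec in design.formulations:
        for model, mean, n in (
            ("static", spec.mean_static, design.replicates_static),
            ("dynamic", spec.mean_dynamic, design.replicates_dynamic),
        ):
            mu, sigma = _lognormal_params(mean, spec.cv)
            amounts = rng.lognormal(mean=mu, sigma=sigma, size=n)
            rows.extend(
                {
                    "formulation": spec.name,
                    "model": model,
                    "replicate": i + 1,
                    "amount_ug_per_cm2": amt,
                    "seed": design.seed,
                }
                for i, amt in enumerate(amounts)
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a record table as CSV with stable float formatting."""
    records.to_csv(path, index=False, float_format="%.6f")
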