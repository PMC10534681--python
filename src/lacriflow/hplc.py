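"""Inverse prediction of drug concentration from HPLC detector response.

The assay reports a linear calibration ``area = slope * c + intercept`` over
a validated range, with a limit of detection (LOD) and limit of
quantification (LOQ) below that range.  This module inverts the line and
flags each back-calculated concentration:

``not_detected``
    below the LOD (reported as 0.0, not NaN, so downstream statistics
    stay defined);
``detected_not_quantifiable``
    in [LOD, LOQ) — the analyte is present but the value is unreliable;
``quantifiable``
    in [LOQ, range_high] (closed on the informative side at both limits);
``out_of_range``
    above the validated range — an error unless extrapolation is
    explicitly allowed.

Concentrations convert to tissue amounts via the extraction volume and,
optionally, to amount per diffusional area.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "CalibrationCurve",
    "Flag",
    "area_to_concentration",
    "batch_quantify",
    "classify_concentration",
    "concentration_to_area",
    "fluconazole_curve",
    "tissue_amount",
]


class Flag(str, Enum):
    QUANTIFIABLE = "quantifiable"
    DETECTED_NOT_QUANTIFIABLE = "detected_not_quantifiable"
    NOT_DETECTED = "not_detected"
    OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear detector response with validated range and detection limits.

    ``slope`` is response per (µg/mL); ``range_low``/``range_high``, ``lod``
    and ``loq`` are in µg/mL.
    """

    slope: float
    intercept: float
    range_low: float
    range_high: float
    lod: float
    loq: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0 < self.lod < self.loq:
            raise ValueError("need 0 < LOD < LOQ")
        if not self.loq <= self.range_low < self.range_high:
            raise ValueError("need LOQ <= range_low < range_high")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        raw = json.loads(Path(path).read_text())
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: dict) -> "CalibrationCurve":
        return cls(
            slope=raw["slope"],
            intercept=raw["intercept"],
            range_low=raw["range_low_ug_per_mL"],
            range_high=raw["range_high_ug_per_mL"],
            lod=raw["lod_ug_per_mL"],
            loq=raw["loq_ug_per_mL"],
        )


def fluconazole_curve() -> CalibrationCurve:
    """The packaged fluconazole UV calibration (linear 0.5–10 µg/mL)."""
    raw = json.loads(
        resources.files("lacriflow.data")
        .joinpath("fluconazole_calibration.json")
        .read_text()
    )
    return CalibrationCurve._from_dict(raw)


def concentration_to_area(curve: CalibrationCurve, concentration: float) -> float:
    """Forward map: expected detector response for a concentration."""
    return curve.slope * concentration + curve.intercept


def area_to_concentration(
    curve: CalibrationCurve,
    area: float,
    *,
    allow_above_range: bool = False,
) -> tuple[float, Flag]:
    """Back-calculate concentration (µg/mL) and flag it against LOD/LOQ/range.

    Negative back-calculated concentrations are reported as 0.0 with
    ``not_detected``.  Above ``range_high`` the linear model is
    extrapolation; this raises unless ``allow_above_range`` is set, in
    which case the value is returned flagged ``out_of_range``.
    """
    if not math.isfinite(area):
        raise ValueError("detector response must be finite")
    c = (area - curve.intercept) / curve.slope
    flag = classify_concentration(curve, c)
    if flag is Flag.NOT_DETECTED:
        # below-detection values are zeroed (not NaN) so downstream
        # statistics stay defined
        return 0.0, flag
    if flag is Flag.OUT_OF_RANGE and not allow_above_range:
        raise ValueError(
            f"back-calculated concentration {c:.3g} µg/mL exceeds the "
            f"validated range ({curve.range_high} µg/mL); dilute and re-assay "
            "or pass allow_above_range=True"
        )
    return c, flag


def classify_concentration(curve: CalibrationCurve, c: float) -> Flag:
    """Flag a concentration against the LOD/LOQ/range boundaries.

    The partition is closed on the informative side: ``c == lod`` is
    detected, ``c == loq`` is quantifiable, ``c == range_high`` is still in
    range.
    """
    if c < curve.lod:
        return Flag.NOT_DETECTED
    if c < curve.loq:
        return Flag.DETECTED_NOT_QUANTIFIABLE
    if c <= curve.range_high:
        return Flag.QUANTIFIABLE
    return Flag.OUT_OF_RANGE


def tissue_amount(
    concentration: float,
    extraction_volume: float = 5.0,
    diffusional_area: float | None = None,
) -> float:
    """Drug amount in the extract (µg), or per diffusional area (µg/cm²).

    ``amount = c x extraction volume`` (default 5 mL of extraction buffer);
    when ``diffusional_area`` (cm²) is given the amount is normalised by it.
    """
    if extraction_volume <= 0:
        raise ValueError("extraction volume must be positive")
    amount = concentration * extraction_volume
    if diffusional_area is not None:
        if diffusional_area <= 0:
            raise ValueError("diffusional area must be positive")
        return amount / diffusional_area
    return amount


def batch_quantify(
    samples: pd.DataFrame,
    curve: CalibrationCurve | None = None,
    *,
    extraction_volume: float = 5.0,
    allow_above_range: bool = False,
) -> pd.DataFrame:
    """Quantify a table of (sample_id, area) detector readings.

    Returns columns sample_id, conc_ug_per_mL, flag, amount_ug.
    """
    for col in ("sample_id", "area"):
        if col not in samples.columns:
            raise ValueError(f"samples table is missing required column {col!r}")
    curve = curve or fluconazole_curve()
    rows = []
    for rec in samples.itertuples(index=False):
        conc, flag = area_to_concentration(
            curve, rec.area, allow_above_range=allow_above_range
        )
        rows.append(
            {
                "sample_id": rec.sample_id,
                "conc_ug_per_mL": conc,
                "flag": flag.value,
                "amount_ug": tissue_amount(conc, extraction_volume),
            }
        )
    return pd.DataFrame(rows)
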