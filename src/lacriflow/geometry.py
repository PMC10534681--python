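"""Donor-compartment prototype geometry and version selection.

Five glass donor-compartment prototypes were iterated for the dynamic eye
model; each is described by nine dimensions (mm): inlet/outlet channel
diameters (d_in, d_out) and heights (H_in, H_out), the inlet/outlet flow
angle θ (a right angle or an acute one), the compartment diameter D_t, an
optional widened base (diameter D_b starting at height H_b, easing eyeball
coupling) and the global height H.

The published comparison table reports the ratios d_out/d_in and H_in/H_out
truncated — not rounded — to two decimals (10.8/11.5 = 0.9391 prints as
0.93); :func:`derived_ratios` reproduces that convention.  The final
prototype combines an acute flow angle, a widened base and the largest
inlet/outlet height gap, which :func:`rank_versions` codifies.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

__all__ = [
    "DonorGeometry",
    "FlowAngle",
    "derived_ratios",
    "load_table1",
    "rank_versions",
    "truncate2",
]


class FlowAngle(str, Enum):
    """Mutual direction of the tear-flow inlet and outlet."""

    RIGHT_ANGLE = "90"
    ACUTE = "<90"


def truncate2(x: float) -> float:
    """Truncate toward zero at two decimals (the printed-table convention)."""
    # tiny epsilon guards against 0.93 stored as 0.9299999... after division
    return math.floor(x * 100.0 + 1e-9) / 100.0


@dataclass(frozen=True)
class DonorGeometry:
    """One donor-compartment prototype (all dimensions in mm)."""

    version: int
    d_in: float
    d_out: float
    h_in: float
    h_out: float
    theta: FlowAngle
    d_t: float
    h: float
    d_b: float | None = None
    h_b: float | None = None

    def __post_init__(self) -> None:
        for name in ("d_in", "d_out", "h_in", "h_out", "d_t", "h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if (self.d_b is None) != (self.h_b is None):
            raise ValueError("base diameter and base height must be given together")
        if self.d_b is not None and (self.d_b <= 0 or self.h_b <= 0):
            raise ValueError("base dimensions must be positive when present")

    @property
    def has_widened_base(self) -> bool:
        return self.d_b is not None


def derived_ratios(geometry: DonorGeometry) -> dict[str, float]:
    """Channel-diameter and channel-height ratios, truncated to 2 decimals."""
    if geometry.d_in <= 0 or geometry.h_out <= 0:
        raise ValueError("ratio denominators must be positive")
    return {
        "d_out/d_in": truncate2(geometry.d_out / geometry.d_in),
        "H_in/H_out": truncate2(geometry.h_in / geometry.h_out),
    }


def load_table1(path: str | Path | None = None) -> list[DonorGeometry]:
    """Load the packaged prototype table (or a CSV with the same columns)."""
    if path is None:
        source = resources.files("lacriflow.data").joinpath("table1.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows = list(csv.DictReader(text.splitlines()))
    out = []
    for row in rows:
        missing = row["D_b"].strip() == "-"
        out.append(
            DonorGeometry(
                version=int(row["version"]),
                d_in=float(row["d_in"]),
                d_out=float(row["d_out"]),
                h_in=float(row["H_in"]),
                h_out=float(row["H_out"]),
                theta=FlowAngle(row["theta"]),
                d_t=float(row["D_t"]),
                h=float(row["H"]),
                d_b=None if missing else float(row["D_b"]),
                h_b=None if missing else float(row["H_b"]),
            )
        )
    return out


def rank_versions(
    candidates: list[DonorGeometry],
) -> tuple[list[DonorGeometry], DonorGeometry]:
    """Order prototypes by the design criteria and return (ranking, selected).

    Candidates with an acute flow angle *and* a widened base are eligible;
    eligible prototypes rank ahead of ineligible ones and among themselves
    by H_in/H_out descending (a larger inlet/outlet height gap prevents
    fluid damming), ties broken by larger base height H_b, then by lower
    version number.  Deterministic and invariant to input order.
    """
    if not candidates:
        raise ValueError("need at least one candidate geometry")

    def key(g: DonorGeometry):
        eligible = g.theta is FlowAngle.ACUTE and g.has_widened_base
        return (
            0 if eligible else 1,
            -(g.h_in / g.h_out),
            -(g.h_b or 0.0),
            g.version,
        )

    ranking = sorted(candidates, key=key)
    return ranking, ranking[0]


def design_report(candidates: list[DonorGeometry]) -> dict:
    """JSON-serialisable report: per-version ratios plus the selection."""
    ranking, selected = rank_versions(candidates)
    return {
        "versions": [
            {
                "version": g.version,
                "theta": g.theta.value,
                "widened_base": g.has_widened_base,
                **derived_ratios(g),
            }
            for g in sorted(candidates, key=lambda g: g.version)
        ],
        "ranking": [g.version for g in ranking],
        "selected_version": selected.version,
    }


def write_design_report(candidates: list[DonorGeometry], path: str | Path) -> None:
    Path(path).write_text(json.dumps(design_report(candidates), indent=2) + "\n")
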