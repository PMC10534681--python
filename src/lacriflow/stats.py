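"""Formulation-comparison statistics for two-arm penetration experiments.

Each arm (static Franz cell, dynamic simulated tear flow) is analysed
separately — the protocols differ in apparatus and temperature, so no
pooled two-way model is attempted.  Per arm the pipeline runs a classical
one-way ANOVA over formulations (computed from definitional sums of
squares), all-pairs multiple comparisons at α = 0.05 (Tukey HSD on the
pooled within-group variance by default; Games–Howell available for
unequal variances), and per-formulation static/dynamic overestimation
ratios — the factor by which the static protocol inflates the apparent
penetrated amount.

Significance is starred in two tiers: ``*`` for adjusted p < 0.05 and
``**`` for adjusted p < 0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "AnovaResult",
    "ComparisonReport",
    "DegenerateDataError",
    "SchemaError",
    "multiple_comparisons",
    "one_way_anova",
    "overestimation_ratios",
    "run_pipeline",
    "significance_stars",
    "validate_records",
]

ALPHA = 0.05
REQUIRED_COLUMNS = ("formulation", "model", "replicate", "amount_ug_per_cm2")


class DegenerateDataError(ValueError):
    """Raised when a dataset cannot support the requested test."""


class SchemaError(ValueError):
    """Raised when a records table lacks a required column."""


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"records table is missing required column {col!r}")
    return records


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < ALPHA:
        return "*"
    return ""


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA summary for a single arm."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p,
            "group_means": self.group_means,
        }


def _groups(
    records: pd.DataFrame,
    value_col: str = "amount_ug_per_cm2",
    group_col: str = "formulation",
) -> dict[str, np.ndarray]:
    groups = {
        str(name): np.asarray(vals, dtype=float)
        for name, vals in records.groupby(group_col, sort=True)[value_col]
    }
    if len(groups) < 2:
        raise DegenerateDataError("need at least two groups to compare")
    for name, vals in groups.items():
        if vals.size < 2:
            raise DegenerateDataError(f"group {name!r} has fewer than 2 replicates")
    return groups


def one_way_anova(
    records: pd.DataFrame,
    value_col: str = "amount_ug_per_cm2",
    group_col: str = "formulation",
) -> AnovaResult:
    """Classical one-way ANOVA from definitional sums of squares.

    SS_between = Σ n_g (ȳ_g − ȳ)²; SS_within = Σ_g Σ_i (y_gi − ȳ_g)²;
    F = MS_between / MS_within with (k−1, N−k) degrees of freedom.
    """
    from scipy import stats as sps

    groups = _groups(records, value_col, group_col)
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    k = len(groups)
    n_total = all_vals.size
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    if ss_within == 0:
        raise DegenerateDataError(
            "zero within-group variance: the F statistic is undefined"
        )
    df_b, df_w = k - 1, n_total - k
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f_stat, df_b, df_w))
    return AnovaResult(
        F=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={name: float(v.mean()) for name, v in groups.items()},
    )


def multiple_comparisons(
    records: pd.DataFrame,
    value_col: str = "amount_ug_per_cm2",
    group_col: str = "formulation",
    method: str = "tukey",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """All-pairs post hoc comparisons with adjusted p-values.

    ``method="tukey"`` (default) applies Tukey's HSD on the pooled
    within-group variance; ``method="games-howell"`` drops the equal
    variance assumption (Welch-type degrees of freedom).  Returns columns
    group1, group2, mean_diff, p_adj, significant, stars.
    """
    groups = _groups(records, value_col, group_col)  # validates shape
    if all(np.ptp(v) == 0 for v in groups.values()):
        raise DegenerateDataError("zero within-group variance in every group")
    if method == "tukey":
        res = pairwise_tukeyhsd(
            endog=records[value_col].to_numpy(dtype=float),
            groups=records[group_col].to_numpy(),
            alpha=alpha,
        )
        pairs = list(combinations([str(g) for g in res.groupsunique], 2))
        out = pd.DataFrame(
            {
                "group1": [a for a, _ in pairs],
                "group2": [b for _, b in pairs],
                "mean_diff": np.asarray(res.meandiffs, dtype=float),
                "p_adj": np.asarray(res.pvalues, dtype=float),
            }
        )
    elif method == "games-howell":
        import pingouin as pg

        gh = pg.pairwise_gameshowell(
            data=records, dv=value_col, between=group_col
        )
        out = pd.DataFrame(
            {
                "group1": gh["A"].astype(str),
                "group2": gh["B"].astype(str),
                "mean_diff": -gh["diff"].astype(float),
                "p_adj": gh["pval"].astype(float),
            }
        )
    else:
        raise ValueError(f"unknown post hoc method {method!r}")
    out["p_adj"] = out["p_adj"].clip(0.0, 1.0)
    out["significant"] = out["p_adj"] < alpha
    out["stars"] = out["p_adj"].map(significance_stars)
    return out


def overestimation_ratios(
    static_records: pd.DataFrame, dynamic_records: pd.DataFrame
) -> pd.Series:
    """Per-formulation mean_static / mean_dynamic penetration ratio.

    A ratio of r means the static protocol overestimates penetration r-fold
    relative to the tear-flow model for that formulation.
    """
    ms = static_records.groupby("formulation")["amount_ug_per_cm2"].mean()
    md = dynamic_records.groupby("formulation")["amount_ug_per_cm2"].mean()
    missing = set(ms.index).symmetric_difference(md.index)
    if missing:
        raise ValueError(
            f"formulations missing from one arm: {sorted(missing)}"
        )
    if (md <= 0).any():
        raise ValueError("dynamic-arm means must be positive to form ratios")
    return (ms / md).rename("overestimation_ratio")


@dataclass(frozen=True)
class ComparisonReport:
    """Full two-arm comparison: ANOVAs, post hoc tables and ratios."""

    anova: dict[str, AnovaResult]
    pairwise: dict[str, pd.DataFrame]
    ratios: pd.Series
    settings: dict

    def to_dict(self) -> dict:
        return {
            "settings": self.settings,
            "anova": {arm: res.to_dict() for arm, res in self.anova.items()},
            "pairwise": {
                arm: tbl.to_dict(orient="records")
                for arm, tbl in self.pairwise.items()
            },
            "overestimation_ratios": self.ratios.to_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_text(self) -> str:
        lines = []
        for arm, res in self.anova.items():
            lines.append(
                f"[{arm}] one-way ANOVA: F({res.df_between}, {res.df_within}) "
                f"= {res.F:.3f}, p = {res.p:.3g}"
            )
            for _, row in self.pairwise[arm].iterrows():
                lines.append(
                    f"  {row.group1} vs {row.group2}: "
                    f"diff = {row.mean_diff:+.3f}, p_adj = {row.p_adj:.3g} "
                    f"{row.stars}".rstrip()
                )
        lines.append("static/dynamic overestimation ratios:")
        for name, ratio in self.ratios.items():
            lines.append(f"  {name}: {ratio:.2f}x")
        return "\n".join(lines) + "\n"


def run_pipeline(
    records: pd.DataFrame,
    *,
    method: str = "tukey",
    settings: dict | None = None,
) -> ComparisonReport:
    """Analyse a tidy two-arm record table end to end.

    Runs a one-way ANOVA and all-pairs post hoc per arm, then the
    static/dynamic overestimation ratios.  Deterministic for a given table.
    """
    validate_records(records)
    arms = {}
    pairwise = {}
    for arm in ("static", "dynamic"):
        sub = records[records["model"] == arm]
        if sub.empty:
            raise DegenerateDataError(f"records contain no {arm!r} arm")
        arms[arm] = one_way_anova(sub)
        pairwise[arm] = multiple_comparisons(sub, method=method)
    ratios = overestimation_ratios(
        records[records["model"] == "static"],
        records[records["model"] == "dynamic"],
    )
    meta = {"alpha": ALPHA, "post_hoc": method}
    if "seed" in records.columns:
        meta["seed"] = sorted(int(s) for s in records["seed"].unique())
    if settings:
        meta.update(settings)
    return ComparisonReport(anova=arms, pairwise=pairwise, ratios=ratios, settings=meta)
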