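"""Condition-comparison statistics for foci readouts.

Per patient, the per-nucleus foci density (or per-focus size) values are
pooled across the images of each condition and compared with a
Kruskal–Wallis rank test (tie-corrected H, chi-squared reference with k−1
degrees of freedom).  When three or more conditions are present and the
omnibus test is significant at α, Dunn's post hoc test on the pooled ranks
follows, Bonferroni-adjusted over the condition pairs.  Intra-tumor
intra-condition variation is summarized as the relative standard deviation
of per-image summary values: 100 × sample SD / mean.

Both rank tests are implemented from their rank formulas; the test suite
cross-checks them against independent reference computations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionComparison",
    "VariationReport",
    "kruskal_wallis",
    "dunn_posthoc",
    "relative_sd",
    "compare_conditions",
    "variation_reports",
    "VARIABLE_COLUMNS",
]

#: analysis variable → column name in the corresponding measurement table
VARIABLE_COLUMNS = {"foci_per_um3": "foci_per_um3", "focus_area_um2": "area_um2"}


@dataclass(frozen=True)
class ConditionComparison:
    patient_id: str
    variable: str
    group_sizes: dict[str, int]
    kw_h: float
    kw_p: float
    significant: bool
    dunn_p: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class VariationReport:
    patient_id: str
    condition: str
    per_image_values: tuple[float, ...]
    relative_sd_percent: float


def _pooled_ranks(groups: list[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray], float]:
    """Mid-ranks of the pooled sample, split back per group, plus Σ(t³−t)."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # average ranks for ties
    split = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, split, tie_sum


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p-value.

    All-identical data (tie correction zero) returns H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need ≥2 non-empty groups")
    n = sum(len(g) for g in groups)
    _, split, tie_sum = _pooled_ranks(groups)
    h = 12.0 / (n * (n + 1)) * sum(len(r) * (r.mean() - (n + 1) / 2.0) ** 2 for r in split)
    correction = 1.0 - tie_sum / (n**3 - n)
    if correction <= 0:
        return 0.0, 1.0
    h /= correction
    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return float(h), p


def dunn_posthoc(
    groups: list,
    names: list[str] | None = None,
    adjustment: str = "bonferroni",
) -> dict[tuple[str, str], float]:
    """Dunn's pairwise z-tests on the pooled ranks, tie-corrected.

    Returns Bonferroni-adjusted two-sided p-values per unordered pair,
    capped at 1.
    """
    if adjustment != "bonferroni":
        raise ValueError(f"unsupported adjustment {adjustment!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3:
        raise ValueError("Dunn's post hoc needs ≥3 groups")
    if names is None:
        names = [f"group{i}" for i in range(k)]
    n = sum(len(g) for g in groups)
    _, split, tie_sum = _pooled_ranks(groups)
    mean_ranks = [r.mean() for r in split]
    var_term = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    n_pairs = k * (k - 1) // 2
    out: dict[tuple[str, str], float] = {}
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_term * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        if se == 0:
            p = 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))) * n_pairs)
        out[(names[i], names[j])] = p
    return out


def relative_sd(per_image_values) -> float:
    """100 × sample SD (n−1) / mean; scale-invariant spread across images."""
    vals = np.asarray(per_image_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need ≥2 per-image values")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("mean is zero: relative SD undefined")
    return float(100.0 * vals.std(ddof=1) / mean)


def compare_conditions(
    table: pd.DataFrame,
    variable: str = "foci_per_um3",
    alpha: float = 0.05,
) -> list[ConditionComparison]:
    """Per-patient Kruskal–Wallis (plus Dunn when ≥3 significant groups).

    ``table`` is a measurement table (one row per nucleus for density, per
    focus for size) with ``patient_id``, ``condition`` and the variable's
    value column.  Values are pooled across a patient's images per
    condition.
    """
    col = VARIABLE_COLUMNS.get(variable)
    if col is None:
        raise ValueError(f"unknown variable {variable!r}; expected one of {sorted(VARIABLE_COLUMNS)}")
    if col not in table.columns:
        raise ValueError(f"table lacks column {col!r}")
    results: list[ConditionComparison] = []
    for pid, sub in table.groupby("patient_id", sort=True):
        conds = sorted(sub["condition"].unique())
        if len(conds) < 2:
            raise ValueError(f"patient {pid} has fewer than 2 conditions")
        groups = [sub.loc[sub["condition"] == c, col].to_numpy(dtype=float) for c in conds]
        if any(len(g) == 0 for g in groups):
            raise ValueError(f"patient {pid} has a condition with zero objects")
        h, p = kruskal_wallis(groups)
        significant = p < alpha
        dunn: dict[tuple[str, str], float] = {}
        if significant and len(conds) >= 3:
            dunn = dunn_posthoc(groups, names=conds)
        results.append(
            ConditionComparison(
                patient_id=str(pid),
                variable=variable,
                group_sizes={c: len(g) for c, g in zip(conds, groups)},
                kw_h=h,
                kw_p=p,
                significant=significant,
                dunn_p=dunn,
            )
        )
    return results


def variation_reports(
    table: pd.DataFrame,
    variable: str = "foci_per_um3",
    per_image_summary: str = "mean",
) -> list[VariationReport]:
    """Relative SD of per-image summaries within each patient × condition."""
    col = VARIABLE_COLUMNS.get(variable)
    if col is None:
        raise ValueError(f"unknown variable {variable!r}")
    if per_image_summary not in ("mean", "median"):
        raise ValueError("per_image_summary must be 'mean' or 'median'")
    agg = getattr(np, per_image_summary)
    out: list[VariationReport] = []
    for (pid, cond), sub in table.groupby(["patient_id", "condition"], sort=True):
        per_image = [
            float(agg(g[col].to_numpy(dtype=float))) for _, g in sub.groupby("image_index", sort=True)
        ]
        out.append(
            VariationReport(
                patient_id=str(pid),
                condition=str(cond),
                per_image_values=tuple(per_image),
                relative_sd_percent=relative_sd(per_image),
            )
        )
    return out
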