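"""Two-group summaries and tests for the metric comparisons.

The in-silico disulfide metrics are compared between hypoxia-induced and
noninduced cargo with the Mann–Whitney U test (rank-based; the metric
distributions are heavily right-skewed). Densitometry summaries use
Student's t. U is reported in the min(U_x, U_y) convention; p-values are
two-sided. The exact null distribution (full enumeration of rank
assignments) is used for small tie-free samples; larger or tied samples
use the normal approximation with tie-corrected variance and continuity
correction. No multiple-testing correction is applied by default (six
raw comparisons are the published convention); a Benjamini–Hochberg
helper is available.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import MetricsTable

__all__ = [
    "TestMethod",
    "GroupSummary",
    "MannWhitneyResult",
    "TTestResult",
    "GroupComparison",
    "summarize",
    "mann_whitney",
    "student_t",
    "compare_groups",
    "compare_all",
    "bh_adjust",
    "EXACT_LIMIT",
]

#: largest pooled sample size for which the exact U distribution is used
EXACT_LIMIT = 14

COMPARABLE_METRICS = (
    "bonds_per_100aa",
    "bond_range",
    "fraction_cys_bonded",
    "n_free_cys",
)


class TestMethod(enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"
    DEGENERATE = "degenerate"


@dataclass(frozen=True)
class GroupSummary:
    """n, mean ± SEM, median and interquartile range of one group."""

    n: int
    mean: float
    sem: float
    median: float
    q25: float
    q75: float


def summarize(values: Sequence[float]) -> GroupSummary:
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("cannot summarize an empty group")
    sem = float(np.std(x, ddof=1) / math.sqrt(x.size)) if x.size > 1 else math.nan
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return GroupSummary(
        n=int(x.size),
        mean=float(np.mean(x)),
        sem=sem,
        median=float(med),
        q25=float(q25),
        q75=float(q75),
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    method: TestMethod


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = EXACT_LIMIT,
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test, U = min(U_x, U_y).

    Exact when n_x + n_y <= ``exact_limit`` and the pooled sample is
    tie-free; otherwise the normal approximation with midranks,
    tie-corrected variance, and continuity correction. Two samples whose
    pooled values are all identical are degenerate: U sits at its null
    mean and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("NaN values must be filtered before testing")
    n_total = x.size + y.size
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return MannWhitneyResult(
            U=x.size * y.size / 2.0, p=1.0, method=TestMethod.DEGENERATE
        )
    ties = np.unique(pooled).size < n_total
    if n_total <= exact_limit and not ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = TestMethod.EXACT
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        method = TestMethod.NORMAL_APPROX
    u_x = float(res.statistic)
    u = min(u_x, x.size * y.size - u_x)
    return MannWhitneyResult(U=u, p=float(min(res.pvalue, 1.0)), method=method)


def student_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t test, df = n_x + n_y - 2, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two values")
    df = int(x.size + y.size - 2)
    sq = (x.size - 1) * np.var(x, ddof=1) + (y.size - 1) * np.var(y, ddof=1)
    if sq == 0:
        if np.mean(x) == np.mean(y):
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        return TTestResult(
            t=math.copysign(math.inf, float(np.mean(x) - np.mean(y))),
            df=df,
            p=0.0,
            degenerate=True,
        )
    res = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


@dataclass(frozen=True)
class GroupComparison:
    """Two-group contrast for one metric within one cargo class."""

    metric: str
    cargo_class: str
    summary_a: GroupSummary
    summary_b: GroupSummary
    U: float
    p: float
    method: TestMethod
    n_omitted: int = 0  # proteins with undefined metric, dropped


def _metric_values(
    table: MetricsTable, metric: str, cargo_class: str, group: str
) -> np.ndarray:
    if metric == "bond_range":
        df = table.bond_ranges
        sel = (df["cargo_class"] == cargo_class) & (
            df["induction_group"] == group
        )
        return df.loc[sel, "bond_range"].to_numpy(dtype=float)
    df = table.per_protein
    sel = (df["cargo_class"] == cargo_class) & (df["induction_group"] == group)
    return df.loc[sel, metric].to_numpy(dtype=float)


def compare_groups(
    table: MetricsTable,
    metric: str,
    cargo_class: str,
    group_a: str = "induced",
    group_b: str = "noninduced",
    pooled_ranges: bool = True,
) -> GroupComparison:
    """Contrast ``metric`` between two induction groups of one cargo class.

    Per-protein values are compared for every metric except
    ``bond_range``, where the pooled per-bond values are used by default
    (``pooled_ranges=False`` switches to per-protein mean ranges).
    Proteins with an undefined value (no cysteines, or no ranged bonds
    for the per-protein-mean convention) are omitted and counted.
    """
    if metric == "bond_range" and not pooled_ranges:
        metric_col = "mean_bond_range"
        a = _metric_values(table, metric_col, cargo_class, group_a)
        b = _metric_values(table, metric_col, cargo_class, group_b)
    else:
        a = _metric_values(table, metric, cargo_class, group_a)
        b = _metric_values(table, metric, cargo_class, group_b)
    n_omitted = int(np.isnan(a).sum() + np.isnan(b).sum())
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError(
            f"empty group for metric {metric!r} in class {cargo_class!r}: "
            f"n_a={a.size}, n_b={b.size}"
        )
    mw = mann_whitney(a, b)
    return GroupComparison(
        metric=metric,
        cargo_class=cargo_class,
        summary_a=summarize(a),
        summary_b=summarize(b),
        U=mw.U,
        p=mw.p,
        method=mw.method,
        n_omitted=n_omitted,
    )


def compare_all(
    table: MetricsTable,
    metrics: Sequence[str] = ("bonds_per_100aa", "bond_range", "fraction_cys_bonded"),
    cargo_classes: Sequence[str] = ("secreted", "membrane"),
    adjust: bool = False,
) -> pd.DataFrame:
    """Run every (metric, cargo class) contrast; tidy one-row-per-test table."""
    rows = []
    for cls in cargo_classes:
        for metric in metrics:
            c = compare_groups(table, metric, cls)
            rows.append(
                {
                    "cargo_class": cls,
                    "metric": metric,
                    "n_a": c.summary_a.n,
                    "mean_a": c.summary_a.mean,
                    "sem_a": c.summary_a.sem,
                    "median_a": c.summary_a.median,
                    "iqr_a": f"{c.summary_a.q25:g}..{c.summary_a.q75:g}",
                    "n_b": c.summary_b.n,
                    "mean_b": c.summary_b.mean,
                    "sem_b": c.summary_b.sem,
                    "median_b": c.summary_b.median,
                    "iqr_b": f"{c.summary_b.q25:g}..{c.summary_b.q75:g}",
                    "U": c.U,
                    "p": c.p,
                    "method": c.method.value,
                    "n_omitted": c.n_omitted,
                }
            )
    out = pd.DataFrame(rows)
    if adjust:
        out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (off by default everywhere)."""
    return sps.false_discovery_control(np.asarray(pvalues, dtype=float))
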