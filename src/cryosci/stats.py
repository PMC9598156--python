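"""Group-comparison statistics for small cytokine cohorts.

The study compares groups of 5-8 animals, which puts it squarely in exact
small-sample territory: the Mann-Whitney test here enumerates the full
permutation distribution of U (midrank tie handling) whenever n1+n2 is small,
confidence intervals for medians are distribution-free order-statistic
intervals, and ROC curves are empirical with the rank-statistic AUC
(AUC * n1 * n2 equals the Mann-Whitney U, ties counting one half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


# --------------------------------------------------------------------------
# exact Mann-Whitney
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # pairs (x_i > y_j) + half the ties
    p_value: float  # two-sided
    n1: int
    n2: int
    method: str  # "exact" or "asymptotic"


@lru_cache(maxsize=32)
def _subset_index(n_total: int, n1: int) -> np.ndarray:
    """All C(n_total, n1) index subsets, as an integer array."""
    return np.array(list(combinations(range(n_total), n1)), dtype=np.intp)


def mann_whitney_exact(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 16
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney test with full enumeration at small n.

    U counts pairs with x > y plus half the tied pairs.  For
    ``n1 + n2 <= exact_limit`` the two-sided p is the permutation-distribution
    mass of |U - n1*n2/2| at least as large as observed (midranks handle
    ties); above the limit a normal approximation with tie correction is
    used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)  # midranks
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 + n2 <= exact_limit:
        idx = _subset_index(n1 + n2, n1)
        rank_sums = ranks[idx].sum(axis=1)
        u_all = rank_sums - n1 * (n1 + 1) / 2.0
        center = n1 * n2 / 2.0
        dev = abs(u_obs - center)
        p = float(np.mean(np.abs(u_all - center) >= dev - 1e-9))
        return MannWhitneyResult(u_obs, p, n1, n2, "exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u_obs, float(res.pvalue), n1, n2, "asymptotic")


# --------------------------------------------------------------------------
# fold changes
# --------------------------------------------------------------------------

def fold_change(median_a: float, median_b: float) -> float:
    """median_a / median_b; NaN (undefined) when the denominator is zero."""
    if median_b < 0 or median_a < 0:
        raise ValueError("medians must be >= 0")
    if median_b == 0:
        return math.nan
    return median_a / median_b


def round_fold(fold: float) -> float:
    """Report-precision rounding: one decimal below 20, integers above."""
    if math.isnan(fold):
        return fold
    return round(fold, 1) if fold < 20 else float(round(fold))


def format_fold(fold: float) -> str:
    if math.isnan(fold):
        return "undefined"
    r = round_fold(fold)
    return f"{r:.1f}" if fold < 20 else f"{r:.0f}"


# --------------------------------------------------------------------------
# distribution-free median CI
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MedianCI:
    lower: float
    upper: float
    level: float  # requested coverage
    coverage: float  # achieved (binomial) coverage
    k: int  # interval is (k-th, (n+1-k)-th) order statistics


def median_ci(sample: Sequence[float], level: float = 0.95) -> MedianCI:
    """Order-statistic (binomial) confidence interval for the median.

    Picks the narrowest symmetric order-statistic interval whose exact
    coverage ``1 - 2*BinomCDF(k-1; n, 1/2)`` reaches ``level``; when no such
    interval exists at the given n, the widest one (sample min to max) is
    returned with its achieved coverage.
    """
    values = np.sort(np.asarray(sample, dtype=float))
    n = values.size
    if n < 3:
        raise ValueError(f"median CI needs n >= 3, got n = {n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    best_k = 1
    for k in range(n // 2, 0, -1):
        cov = 1.0 - 2.0 * sps.binom.cdf(k - 1, n, 0.5)
        if cov >= level:
            best_k = k
            break
    coverage = float(1.0 - 2.0 * sps.binom.cdf(best_k - 1, n, 0.5))
    return MedianCI(float(values[best_k - 1]), float(values[n - best_k]), level, coverage, best_k)


# --------------------------------------------------------------------------
# empirical ROC
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC operating points and the trapezoidal AUC.

    Convention: higher analyte values indicate the positive (adverse) class;
    an operating point at threshold t calls values >= t positive.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def empirical_roc(negatives: Sequence[float], positives: Sequence[float]) -> ROCCurve:
    """ROC of the rule "value >= threshold => positive" over all thresholds."""
    neg = np.asarray(negatives, dtype=float)
    pos = np.asarray(positives, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both classes must be non-empty")
    thresholds = np.unique(np.concatenate([neg, pos]))[::-1]
    fpr = np.concatenate([[0.0], [np.mean(neg >= t) for t in thresholds]])
    tpr = np.concatenate([[0.0], [np.mean(pos >= t) for t in thresholds]])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr, tpr, thresholds, auc)


# --------------------------------------------------------------------------
# cohort-level comparisons
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    analyte: str
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    fold_change: float
    u: float
    p_value: float
    ci_a: Optional[MedianCI]
    ci_b: Optional[MedianCI]


def _group_values(cohort: pd.DataFrame, analyte: str, group: str) -> np.ndarray:
    values = cohort.loc[
        (cohort["analyte"] == analyte) & (cohort["group"] == group), "value_pg_ml"
    ].to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError(f"no values for analyte {analyte!r} in group {group!r}")
    return values


def compare_groups(
    cohort: pd.DataFrame,
    analyte: str,
    group_a: str,
    group_b: str,
    ci_level: float = 0.95,
) -> GroupComparison:
    """Medians, fold change, exact Mann-Whitney and per-group median CIs."""
    a = _group_values(cohort, analyte, group_a)
    b = _group_values(cohort, analyte, group_b)
    mw = mann_whitney_exact(a, b)
    return GroupComparison(
        analyte=analyte,
        group_a=group_a,
        group_b=group_b,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        fold_change=fold_change(float(np.median(a)), float(np.median(b))),
        u=mw.u,
        p_value=mw.p_value,
        ci_a=median_ci(a, ci_level) if a.size >= 3 else None,
        ci_b=median_ci(b, ci_level) if b.size >= 3 else None,
    )


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte summary mirroring the published panel layout.

    One row per analyte: "median [min; max]" per group plus the exact
    Mann-Whitney p values of the three pairwise group comparisons.
    """
    groups = [g for g in ("intact", "favorable", "adverse") if g in set(cohort["group"])]
    rows = []
    for analyte in pd.unique(cohort["analyte"]):
        row: dict[str, object] = {"analyte": analyte}
        values = {g: _group_values(cohort, analyte, g) for g in groups}
        for g, v in values.items():
            row[g] = f"{np.median(v):g} [{v.min():g}; {v.max():g}]"
        for ga, gb in (("favorable", "intact"), ("adverse", "intact"), ("favorable", "adverse")):
            if ga in values and gb in values:
                row[f"p_{ga}_vs_{gb}"] = mann_whitney_exact(values[ga], values[gb]).p_value
        rows.append(row)
    return pd.DataFrame(rows)
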