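"""Nonparametric statistical battery used by the cohort analysis.

Thin, contract-enforcing wrappers around scipy.stats: Mann-Whitney U
(exact enumeration for small tie-free samples, otherwise normal
approximation with tie and continuity correction), Spearman rank
correlation with midrank ties, and the two-sided Fisher exact test.
All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "MannWhitneyResult",
    "SpearmanResult",
    "mann_whitney",
    "spearman",
    "fisher_exact",
    "median_iqr",
]

#: Combined sample size at or below which the exact U distribution is used
#: (only when there are no ties; ties force the corrected approximation).
EXACT_SWITCH_N = 20


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of the U null distribution when
    ``len(a) + len(b) <= 20`` and the pooled sample is tie-free; otherwise
    the normal approximation with midrank tie correction and continuity
    correction.  The U statistic reported is for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = (a.size + b.size) <= EXACT_SWITCH_N and not _has_ties(
        np.concatenate([a, b])
    )
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return MannWhitneyResult(
        u=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "asymptotic",
    )


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation (midrank ties), two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho is undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return SpearmanResult(rho=float(res.statistic), p_value=float(res.pvalue))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities of all tables (fixed margins) whose
    probability does not exceed the observed table's.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must contain non-negative integer counts")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


def median_iqr(x) -> tuple[float, float, float]:
    """Median and (Q25, Q75) with linear (type-7) interpolation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return float(med), float(q25), float(q75)
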