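"""Shared statistical primitives.

Every hypothesis test in the toolkit funnels through this module so that the
small-sample behaviour (exact rank-sum null for small tie-free samples) and
the multiple-testing correction are uniform across analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "ranksum", "bh_fdr", "pearson", "EXACT_MAX_N"]

#: per-group size at or below which the exact rank-sum null is enumerated
#: (tie-free samples only); above it a tie-corrected normal approximation
#: with continuity correction is used.
EXACT_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample test.

    ``direction`` is ``"x"`` or ``"y"`` for the sample with the higher mean
    rank, or ``None`` when mean ranks tie. ``method_note`` records whether the
    exact or the approximate null was used.
    """

    statistic: float
    p: float
    direction: str | None
    method_note: str


def ranksum(x, y, exact_max_n: int = EXACT_MAX_N) -> TestResult:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses exact enumeration of the U null when both samples have at most
    ``exact_max_n`` observations and the pooled data are tie-free; otherwise a
    normal approximation with tie and continuity corrections.

    Parameters
    ----------
    x, y : array-like
        The two independent samples; both must be non-empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("ranksum requires both samples to be non-empty")

    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    mean_rank_x = float(ranks[: x.size].mean())
    mean_rank_y = float(ranks[x.size :].mean())
    if mean_rank_x > mean_rank_y:
        direction = "x"
    elif mean_rank_y > mean_rank_x:
        direction = "y"
    else:
        direction = None

    if np.all(pooled == pooled[0]):
        # degenerate: every observation identical; no evidence either way
        return TestResult(x.size * y.size / 2.0, 1.0, None, "degenerate (all values equal)")

    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and x.size <= exact_max_n and y.size <= exact_max_n:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        note = "exact"
    else:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        note = "normal approximation, tie/continuity corrected"
    return TestResult(float(res.statistic), min(float(res.pvalue), 1.0), direction, note)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value (df = n-2).

    Returns ``(nan, nan)`` for constant input, flagging the correlation as
    undefined rather than raising, so callers can drop such pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson requires equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    cc, p = _sps.pearsonr(x, y)
    return float(cc), float(p)
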