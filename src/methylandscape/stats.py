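"""Rank-sum testing used throughout the landscape analyses.

The two-sided Wilcoxon rank-sum (Mann-Whitney U) test compares bin-level
quantities between two groups of genomic bins. The exact null distribution is
used whenever the smaller sample is small enough and the data are tie-free;
otherwise the normal approximation with tie and continuity correction is
used. The result records which method produced the p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # "exact", "asymptotic" or "degenerate"

    def __iter__(self):  # allow tuple-unpacking (stat, p)
        yield self.statistic
        yield self.p_value


def wilcoxon_rank_sum(x, y, exact_max_n: int = 25) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of ``x`` versus ``y``.

    Exact enumeration when min(len(x), len(y)) <= ``exact_max_n`` and there
    are no ties across the pooled sample; normal approximation with tie
    correction otherwise. If every pooled value is identical the test is
    degenerate and p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all values identical in both samples; rank-sum test degenerate")
        return RankSumResult(x.size * y.size / 2.0, 1.0, "degenerate")
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = _stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(min(res.pvalue, 1.0)), method)
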