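"""Two-group comparisons of per-individual metrics.

Per-individual values (WID, BID, aggregate ANO) are compared between two
density conditions with the Wilcoxon rank-sum (Mann-Whitney) test and
summarised by median and inter-quartile range.  The W statistic reported is
the rank sum of the first sample minus ``n1*(n1+1)/2`` (so 0 <= W <= n1*n2),
and the exact two-sided p-value is used whenever both samples have fewer
than 50 values and there are no ties; otherwise the normal approximation
with tie-corrected variance and continuity correction applies.  Quartiles
interpolate order statistics at position ``h = (n-1)p + 1``.  One test per
metric, no multiplicity adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("hootid.group_compare")

__all__ = ["RankSumResult", "GroupSummary", "ComparisonResult",
           "wilcoxon_rank_sum", "median_iqr", "compare_conditions"]

EXACT_LIMIT = 50


@dataclass
class RankSumResult:
    w_statistic: float
    p_two_sided: float
    method: str  # 'exact' or 'normal_approx'
    n1: int
    n2: int


@dataclass
class GroupSummary:
    group_label: str
    n: int
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass
class ComparisonResult:
    metric: str
    summaries: list
    test: RankSumResult
    alpha: float

    @property
    def significant(self) -> bool:
        return self.test.p_two_sided < self.alpha


def _has_ties(x, y):
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def wilcoxon_rank_sum(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two independent samples.

    Exact when both n < 50 and the pooled sample is tie-free (two-sided p
    as twice the smaller tail, clipped at 1); otherwise the tie-corrected
    normal approximation with continuity correction.  Mid-ranks are used
    for ties.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = x.size < EXACT_LIMIT and y.size < EXACT_LIMIT and not _has_ties(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return RankSumResult(
        w_statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_approx",
        n1=x.size, n2=y.size,
    )


def median_iqr(x, group_label: str = "") -> GroupSummary:
    """Median and quartiles (linear interpolation of order statistics)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("sample must be non-empty")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return GroupSummary(group_label=str(group_label), n=x.size,
                        median=float(med), q1=float(q1), q3=float(q3))


def compare_conditions(values, groups, metric: str = "",
                       alpha: float = 0.05) -> ComparisonResult:
    """Compare one per-individual metric between exactly two conditions.

    ``values`` are the per-individual statistics, ``groups`` the matching
    condition labels.  Returns per-group summaries, the rank-sum test and a
    significance flag at ``alpha``.  Groups with fewer than 2 individuals
    are warned about but still tested.
    """
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups differ in length")
    labels = list(dict.fromkeys(groups.tolist()))  # first-appearance order
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    samples = [values[groups == g] for g in labels]
    for g, s in zip(labels, samples):
        if s.size < 2:
            logger.warning("group %r has only %d individual(s)", g, s.size)
    test = wilcoxon_rank_sum(samples[0], samples[1])
    summaries = [median_iqr(s, group_label=g) for g, s in zip(labels, samples)]
    return ComparisonResult(metric=metric, summaries=summaries, test=test, alpha=alpha)
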