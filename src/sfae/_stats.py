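"""Shared statistical engine: rank-sum test and multiple-testing correction.

The Wilcoxon rank-sum (Mann-Whitney) test is used throughout the toolkit
(group comparisons of CR variation, motif-density enrichment). Small
samples (both groups <= 8) are handled by exact enumeration of all
C(n_a + n_b, n_a) rank assignments on midranks, which is valid in the
presence of ties; larger samples use the tie-corrected normal
approximation from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

EXACT_MAX_GROUP = 8


@dataclass
class RankSumResult:
    statistic: float  # rank sum of group a (midranks)
    p_value: float
    method: str  # "exact" or "asymptotic"


def _exact_rank_sum_p(ranks: np.ndarray, n_a: int, observed: float,
                      alternative: str) -> float:
    """Exact p by enumerating every choice of n_a ranks for group a.

    Two-sided p is the doubled smaller tail probability, capped at 1.
    """
    idx = range(len(ranks))
    total = 0
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for comb in combinations(idx, n_a):
        s = ranks[list(comb)].sum()
        total += 1
        if s <= observed + eps:
            n_le += 1
        if s >= observed - eps:
            n_ge += 1
    p_less = n_le / total
    p_greater = n_ge / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def rank_sum_test(a, b, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum test of two independent samples.

    Parameters
    ----------
    a, b
        Value sequences; each must have >= 2 observations.
    alternative
        ``"two-sided"`` (default), ``"less"`` (a tends smaller) or
        ``"greater"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if alternative not in {"two-sided", "less", "greater"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    w_a = float(ranks[: a.size].sum())
    if a.size <= EXACT_MAX_GROUP and b.size <= EXACT_MAX_GROUP:
        p = _exact_rank_sum_p(ranks, a.size, w_a, alternative)
        return RankSumResult(statistic=w_a, p_value=p, method="exact")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return RankSumResult(statistic=w_a, p_value=float(res.pvalue), method="asymptotic")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values, preserving input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
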