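"""Rank-based two-sample and k-sample tests on small groups.

With four replicates per zone the asymptotic Wilcoxon null is a poor
approximation (the smallest attainable two-sided p for 4-vs-4 is 2/70),
so the two-sample test enumerates the exact mid-rank permutation null
whenever both groups have at most ``EXACT_MAX`` members; larger groups
fall back to the tie-corrected normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

EXACT_MAX = 8
_EPS = 1e-9


@dataclass
class RankSumResult:
    statistic: float        # rank sum of the first group (mid-ranks)
    p_value: float
    method: str             # "exact" | "normal"
    alternative: str
    median_diff: float      # median(x) - median(y)
    n_x: int
    n_y: int


def rank_sum_test(x, y, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum test, exact by enumeration for small groups.

    The exact null enumerates all C(n_x+n_y, n_x) assignments of the
    pooled mid-ranks to the first group, so tied observations are handled
    without approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n_x].sum())
    mu = n_x * (n_x + n_y + 1) / 2.0

    if max(n_x, n_y) <= EXACT_MAX:
        total = comb(n_x + n_y, n_x)
        n_ge = n_le = n_extreme = 0
        dev_obs = abs(w_obs - mu)
        for idx in combinations(range(n_x + n_y), n_x):
            w = ranks[list(idx)].sum()
            if w >= w_obs - _EPS:
                n_ge += 1
            if w <= w_obs + _EPS:
                n_le += 1
            if abs(w - mu) >= dev_obs - _EPS:
                n_extreme += 1
        if alternative == "greater":
            p = n_ge / total
        elif alternative == "less":
            p = n_le / total
        else:
            p = min(1.0, n_extreme / total)
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative=alternative,
                                 method="asymptotic")
        p = float(res.pvalue)
        method = "normal"

    return RankSumResult(w_obs, p, method, alternative,
                         float(np.median(x) - np.median(y)), n_x, n_y)


@dataclass
class GroupComparison:
    """Global Kruskal-Wallis plus pairwise rank-sum tests on named groups."""

    kruskal_h: float
    kruskal_p: float
    groups: list[str]
    group_means: dict[str, float]
    pairwise: dict[tuple[str, str], RankSumResult]
    # both orderings: (a, b) -> 100*(mean_a - mean_b)/mean_b, b the reference
    percent_change: dict[tuple[str, str], float]
    excluded: list[str]


def compare_groups(values: dict[str, np.ndarray],
                   min_group_size: int = 2) -> GroupComparison:
    """Kruskal-Wallis across groups and exact pairwise Wilcoxon tests.

    Groups with fewer than ``min_group_size`` members are excluded with a
    warning rather than failing the whole comparison. The percent change
    for pair (a, b) uses b as the reference: 100*(mean_a - mean_b)/mean_b.
    """
    import logging

    usable = {g: np.asarray(v, dtype=float) for g, v in values.items()
              if len(v) >= min_group_size}
    excluded = sorted(set(values) - set(usable))
    if excluded:
        logging.getLogger(__name__).warning(
            "compare_groups: excluding undersized groups %s", excluded)
    if len(usable) < 2:
        raise ValueError("need at least two groups with enough samples")
    names = sorted(usable)
    h, p = stats.kruskal(*[usable[g] for g in names])
    pairwise = {}
    pct = {}
    means = {g: float(np.mean(usable[g])) for g in names}
    for a, b in combinations(names, 2):
        pairwise[(a, b)] = rank_sum_test(usable[a], usable[b])
        for u, v in ((a, b), (b, a)):
            pct[(u, v)] = (100.0 * (means[u] - means[v]) / means[v]
                           if means[v] != 0 else float("nan"))
    return GroupComparison(float(h), float(p), names, means, pairwise, pct,
                           excluded)
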