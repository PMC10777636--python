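"""Community-level comparison: Bray-Curtis distances, PCoA, ANOSIM.

The ordination is classical metric scaling; Bray-Curtis matrices are
generally non-Euclidean, so negative eigenvalues can appear. By default
they are dropped from both the coordinates and the explained-variance
denominator (the uncorrected convention is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sympy.utilities.iterables import multiset_permutations


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray     # samples x axes
    explained: np.ndarray       # proportion per axis, non-increasing
    eigenvalues: np.ndarray     # all eigenvalues, descending
    negative_eigenvalue_mass: float


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    exhaustive: bool
    seed: int | None


def bray_curtis(table) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns."""
    x = table.values.T  # samples x taxa
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero sample(s) make Bray-Curtis undefined: {zero}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def pcoa(d: DistanceMatrix, drop_negative: bool = True) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues. ``drop_negative=False``
    includes negative eigenvalues in the explained-variance denominator
    (coordinates are always restricted to positive eigenvalues).
    """
    n = d.n
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    d2 = d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(abs(evals[0]), abs(evals[-1])) * 1e-12
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    denom = evals[pos].sum() if drop_negative else np.abs(evals).sum()
    explained = evals[pos] / denom
    neg_mass = float(-evals[evals < -tol].sum())
    return PcoaResult(list(d.sample_ids), coords, explained, evals, neg_mass)


def _n_distinct_assignments(counts: Sequence[int]) -> int:
    total = factorial(sum(counts))
    for c in counts:
        total //= factorial(c)
    return total


def anosim(d: DistanceMatrix, groups: Sequence[str],
           n_permutations: int = 9999, seed: int | None = None,
           exhaustive_limit: int = 20000) -> AnosimResult:
    """Analysis of similarities with a label-permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2), where
    ranks (mid-ranks for ties) are taken over all M = n(n-1)/2 pairwise
    distances. When the number of distinct label assignments is at most
    ``exhaustive_limit`` the null is enumerated exactly; otherwise
    ``n_permutations`` random permutations are drawn and
    p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations).
    """
    labels = np.asarray(groups)
    if labels.shape[0] != d.n:
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if np.any(counts < 2):
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 members: {small}")

    condensed = d.condensed()
    ranks = stats.rankdata(condensed)
    iu = np.triu_indices(d.n, k=1)

    def r_for(lab: np.ndarray) -> float:
        same = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~same].mean() - ranks[same].mean())
                     / (len(ranks) / 2.0))

    r_obs = r_for(labels)
    n_assign = _n_distinct_assignments(counts)

    if n_assign <= exhaustive_limit:
        n_ge = 0
        for perm in multiset_permutations(list(labels)):
            if r_for(np.asarray(perm)) >= r_obs - 1e-12:
                n_ge += 1
        return AnosimResult(r_obs, n_ge / n_assign, n_assign, True, seed)

    rng = np.random.default_rng(seed)
    n_ge = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if r_for(lab) >= r_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return AnosimResult(r_obs, p, n_permutations, False, seed)
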