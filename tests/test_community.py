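from itertools import combinations
from math import comb

import numpy as np
import pytest

from coremf.community import DistanceMatrix, anosim, bray_curtis, pcoa
from coremf.tables import OtuTable


def make_table(values):
    values = np.asarray(values, dtype=float)
    return OtuTable([f"O{i}" for i in range(values.shape[0])],
                    [f"S{j}" for j in range(values.shape[1])], values)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(make_table([[3, 3], [1, 1]]))
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        d = bray_curtis(make_table([[5, 0], [0, 7]]))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_textbook_example(self):
        # u=(6,2), v=(2,2): 1 - 2*(2+2)/(8+4) = 1/3
        d = bray_curtis(make_table([[6, 2], [2, 2]]))
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(make_table([[1, 0], [2, 0]]))

    def test_matches_scikit_bio(self, rng):
        vals = rng.integers(0, 20, size=(15, 6)) + 1
        d = bray_curtis(make_table(vals))
        from skbio.diversity import beta_diversity
        ref = beta_diversity("braycurtis", vals.T.astype(float))
        np.testing.assert_allclose(d.values, ref.data, atol=1e-12)


class TestPcoa:
    def test_euclidean_input_reproduced(self, rng):
        pts = rng.normal(size=(12, 2))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"S{i}" for i in range(12)], dm))
        coords = res.coordinates[:, :2]
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(rec, dm, atol=1e-8)
        assert np.all(np.diff(res.explained) <= 1e-12)

    def test_regular_simplex_equal_axes(self):
        n = 5
        dm = 1.0 - np.eye(n)
        res = pcoa(DistanceMatrix([f"S{i}" for i in range(n)], dm))
        np.testing.assert_allclose(res.explained, res.explained[0], atol=1e-9)

    def test_eigenvalues_match_dense_solver(self, rng):
        vals = rng.integers(1, 30, size=(20, 8))
        d = bray_curtis(make_table(vals))
        res = pcoa(d)
        # independent double-centering + scipy dense eigensolver
        from scipy.linalg import eigh
        n = d.n
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d.values ** 2) @ j
        ref = np.sort(eigh(b)[0])[::-1]
        np.testing.assert_allclose(res.eigenvalues, ref, atol=1e-10)

    def test_explained_matches_scikit_bio(self, rng):
        vals = rng.integers(1, 30, size=(25, 9))
        d = bray_curtis(make_table(vals))
        res = pcoa(d)
        import skbio
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.sample_ids))
        k = len(res.explained)
        np.testing.assert_allclose(
            res.explained,
            (ref.eigvals[:k] / ref.eigvals[ref.eigvals > 0].sum()).to_numpy(),
            atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(["a", "b"], np.array([[0, 1.], [1., 0]])))


def brute_force_anosim_r(dvals, labels):
    """Direct rank formula, independent pair loops."""
    from scipy.stats import rankdata
    n = len(labels)
    pairs = list(combinations(range(n), 2))
    dists = [dvals[i, j] for i, j in pairs]
    ranks = rankdata(dists)
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2)


class TestAnosim:
    @staticmethod
    def _dm(rng, n):
        a = rng.random((n, n))
        d = (a + a.T) / 2
        np.fill_diagonal(d, 0)
        return DistanceMatrix([f"S{i}" for i in range(n)], d)

    def test_perfect_separation_r_one(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0)
        res = anosim(DistanceMatrix(list("abcd"), d), ["g1", "g1", "g2", "g2"])
        assert res.r == pytest.approx(1.0)

    def test_r_matches_brute_force(self, rng):
        d = self._dm(rng, 8)
        labels = ["a", "a", "a", "b", "b", "b", "b", "a"]
        res = anosim(d, labels)
        assert res.r == pytest.approx(brute_force_anosim_r(d.values, labels),
                                      abs=1e-12)

    def test_r_matches_scikit_bio(self, rng):
        import skbio
        d = self._dm(rng, 9)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = anosim(d, labels)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(d.values, ids=d.sample_ids), labels,
            permutations=0)
        assert res.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_exhaustive_p_equals_enumeration(self, rng):
        d = self._dm(rng, 6)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = anosim(d, labels)
        assert res.exhaustive and res.n_permutations == comb(6, 3)
        # independent enumeration over all 20 assignments
        r_obs = brute_force_anosim_r(d.values, labels)
        count = 0
        for pos in combinations(range(6), 3):
            perm = ["b"] * 6
            for i in pos:
                perm[i] = "a"
            if brute_force_anosim_r(d.values, perm) >= r_obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / 20)

    def test_monotone_transform_invariance(self, rng):
        d = self._dm(rng, 7)
        labels = ["a", "a", "a", "b", "b", "b", "b"]
        r1 = anosim(d, labels).r
        d2 = DistanceMatrix(d.sample_ids, np.sqrt(d.values))
        assert anosim(d2, labels).r == pytest.approx(r1, abs=1e-12)

    def test_sampled_p_reproducible(self, rng):
        d = self._dm(rng, 12)
        labels = ["a", "b", "c"] * 4
        res1 = anosim(d, labels, n_permutations=200, seed=5,
                      exhaustive_limit=10)
        res2 = anosim(d, labels, n_permutations=200, seed=5,
                      exhaustive_limit=10)
        assert res1.p == res2.p and not res1.exhaustive

    def test_single_group_rejected(self, rng):
        d = self._dm(rng, 4)
        with pytest.raises(ValueError):
            anosim(d, ["a"] * 4)
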