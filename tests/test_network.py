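import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coremf.network import (NetworkParams, adjacency, cluster_abundance,
                            cluster_modules, connectivity, hub_taxa,
                            module_eigengene, module_membership,
                            pick_soft_threshold, scale_free_fit, tom,
                            taxon_profiles, build_network)
from coremf.tables import OtuTable


def brute_force_tom(a):
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_symmetric_adjacency(rng, n=8):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_identical_profiles_full_edge(self):
        x = np.vstack([np.arange(6.0), np.arange(6.0)])
        for beta in (1, 5, 10):
            a = adjacency(x, beta, NetworkParams(network_type="unsigned"))
            assert a[0, 1] == pytest.approx(1.0)

    def test_negative_correlation_unsigned_vs_signed(self):
        x = np.vstack([np.arange(6.0), -np.arange(6.0)])
        au = adjacency(x, 10, NetworkParams(network_type="unsigned"))
        a_s = adjacency(x, 10, NetworkParams(network_type="signed"))
        assert au[0, 1] == pytest.approx(1.0)
        assert a_s[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_half_negative_correlation_power_ten(self):
        # x2 = -0.5*x1 + sqrt(0.75)*o with o orthogonal, so cor = -0.5
        x1 = np.array([1.0, -1.0, 1.0, -1.0])
        o = np.array([1.0, 1.0, -1.0, -1.0])
        x2 = -0.5 * x1 + np.sqrt(0.75) * o
        a = adjacency(np.vstack([x1, x2]), 10,
                      NetworkParams(network_type="unsigned"))
        assert a[0, 1] == pytest.approx(9.765625e-4, rel=1e-9)

    def test_unsigned_invariant_to_profile_sign_flip(self, rng):
        x = rng.normal(size=(6, 10))
        flipped = x.copy()
        flipped[2] *= -1
        pu = NetworkParams(network_type="unsigned")
        np.testing.assert_allclose(adjacency(x, 6, pu),
                                   adjacency(flipped, 6, pu), atol=1e-12)
        ps = NetworkParams(network_type="signed")
        assert not np.allclose(adjacency(x, 6, ps), adjacency(flipped, 6, ps))


class TestTom:
    def test_zero_adjacency(self):
        a = np.eye(5)
        t = tom(a)
        assert np.all(t[~np.eye(5, dtype=bool)] == 0)
        assert np.all(np.diag(t) == 1)

    def test_single_edge_hand_value(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        t = tom(a)
        # (L + A) / (min(k) + 1 - A) = (0 + 1) / (1 + 1 - 1) = 1
        assert t[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_symmetric_adjacency(rng)
        np.testing.assert_allclose(tom(a), brute_force_tom(a), atol=1e-12)

    def test_range_and_symmetry(self, rng):
        a = random_symmetric_adjacency(rng, 12)
        t = tom(a)
        assert np.all((t >= 0) & (t <= 1 + 1e-12))
        np.testing.assert_allclose(t, t.T, atol=1e-15)

    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom(a)


class TestScaleFree:
    def test_power_law_degree_sequence_fits(self):
        n = 1000
        u = (np.arange(n) + 0.5) / n
        k = 1.0 / (1.0 - u * (1 - 1 / 20))  # p(k) ~ k^-2 on [1, 20]
        r2, slope = scale_free_fit(k)
        assert r2 >= 0.999
        assert slope < 0

    def test_noise_profiles_take_warning_path(self, caplog):
        rng = np.random.default_rng(0)
        profiles = rng.standard_normal((50, 12))
        with caplog.at_level("WARNING", logger="coremf.network"):
            report = pick_soft_threshold(profiles)
        assert not report.reached_target
        assert max(report.r2) < 0.9
        assert any("no candidate power" in r.message for r in caplog.records)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(np.random.default_rng(0).random((5, 12)))


class TestClustering:
    @staticmethod
    def _block_tom(sizes, within=0.95, between=0.02):
        n = sum(sizes)
        t = np.full((n, n), between)
        start = 0
        for s in sizes:
            t[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(t, 1.0)
        return t

    def test_two_blocks_recovered(self):
        t = self._block_tom([25, 20])
        labels = cluster_modules(t, NetworkParams(min_cluster_size=10))
        assert set(labels) == {1, 2}
        assert (labels[:25] == 1).all() and (labels[25:] == 2).all()

    def test_labels_ordered_by_descending_size(self):
        t = self._block_tom([15, 30])
        labels = cluster_modules(t, NetworkParams(min_cluster_size=10))
        assert (labels[15:] == 1).all() and (labels[:15] == 2).all()

    def test_invariant_to_taxon_order(self, rng):
        t = self._block_tom([20, 15, 10])
        perm = rng.permutation(t.shape[0])
        labels = cluster_modules(t, NetworkParams(min_cluster_size=8))
        permuted = cluster_modules(t[np.ix_(perm, perm)],
                                   NetworkParams(min_cluster_size=8))
        # same partition under the permutation
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels[perm], permuted) == pytest.approx(1.0)

    def test_min_size_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster_modules(np.eye(5), NetworkParams(min_cluster_size=10))


class TestEigengene:
    def test_identical_members_perfect_correlation(self):
        base = np.sin(np.linspace(0, 3, 8))
        profiles = pd.DataFrame(np.vstack([base] * 4),
                                index=list("abcd"),
                                columns=[f"S{i}" for i in range(8)])
        eig = module_eigengene(profiles, np.ones(4, dtype=int))
        kme = module_membership(profiles, eig)
        np.testing.assert_allclose(np.abs(kme[1]), 1.0, atol=1e-10)

    def test_orientation_mean_own_kme_nonnegative(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(10, 9)))
        labels = np.array([1] * 5 + [2] * 5)
        eig = module_eigengene(profiles, labels)
        kme = module_membership(profiles, eig)
        for q, members in [(1, range(5)), (2, range(5, 10))]:
            assert kme.iloc[list(members)][q].mean() >= 0

    def test_matches_rank_one_factorization_oracle(self, rng):
        x = rng.normal(size=(3, 7))
        profiles = pd.DataFrame(x)
        eig = module_eigengene(profiles, np.ones(3, dtype=int))
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        # independent oracle: eigenvector of the sample covariance Z^T Z
        w, v = np.linalg.eigh(z.T @ z)
        lead = v[:, np.argmax(w)]
        got = eig[1].to_numpy()
        assert abs(abs(lead @ got)) == pytest.approx(1.0, abs=1e-10)

    def test_eigengene_maximizes_explained_variance(self, rng):
        x = rng.normal(size=(6, 8))
        profiles = pd.DataFrame(x)
        eig = module_eigengene(profiles, np.ones(6, dtype=int))[1].to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        best = float(np.linalg.norm(z @ eig))
        for _ in range(200):
            v = rng.normal(size=8)
            v /= np.linalg.norm(v)
            assert np.linalg.norm(z @ v) <= best + 1e-9


class TestHubTaxa:
    def test_threshold_is_strict(self):
        kme = pd.DataFrame({1: [0.9, 0.95, 0.2]}, index=list("abc"))
        hubs = hub_taxa(kme, np.array([1, 1, 1]), threshold=0.9)
        assert hubs[1] == ["b"]  # 0.9 exactly is not a hub


class TestClusterAbundance:
    def test_single_member_cluster_is_zscore(self):
        x = np.array([[1.0, 2.0, 3.0, 6.0]])
        profiles = pd.DataFrame(x, index=["a"], columns=list("wxyz"))
        ca = cluster_abundance(profiles, np.array([1]))
        z = (x[0] - x[0].mean()) / x[0].std()
        np.testing.assert_allclose(ca.loc[1].to_numpy(), z, atol=1e-12)

    def test_rows_have_zero_mean(self, rng):
        profiles = pd.DataFrame(rng.random((12, 6)))
        labels = np.array([1] * 6 + [2] * 6)
        ca = cluster_abundance(profiles, labels)
        np.testing.assert_allclose(ca.to_numpy().mean(axis=1), 0, atol=1e-12)

    def test_matches_brute_force_average(self, rng):
        x = rng.random((5, 7))
        profiles = pd.DataFrame(x)
        labels = np.array([1, 1, 1, 2, 2])
        ca = cluster_abundance(profiles, labels)
        zs = [(x[i] - x[i].mean()) / x[i].std() for i in range(3)]
        np.testing.assert_allclose(ca.loc[1].to_numpy(),
                                   np.mean(zs, axis=0), atol=1e-12)


class TestProfiles:
    def test_full_table_passthrough(self, rng):
        vals = rng.integers(1, 9, size=(6, 5)).astype(float)
        table = OtuTable([f"O{i}" for i in range(6)],
                         [f"S{j}" for j in range(5)], vals)
        profiles, excluded = taxon_profiles(table)
        assert excluded == []
        np.testing.assert_allclose(profiles.to_numpy(),
                                   vals / vals.sum(0), atol=1e-12)

    def test_constant_taxon_excluded(self):
        vals = np.array([[1.0, 1, 1, 1], [1, 2, 3, 4], [2, 3, 1, 5]])
        vals[0] = 0.0
        table = OtuTable(["a", "b", "c"], list("wxyz"), vals)
        profiles, excluded = taxon_profiles(table)
        assert excluded == ["a"]
        assert list(profiles.index) == ["b", "c"]
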