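import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from coremf.drivers import (DEFAULT_TROPHIC_MAP, _forest_oob_state, _oob_mse,
                            compare_cluster_abundance_by_zone,
                            compare_core_importance, ols_cluster_emf,
                            rf_importance, trophic_ratio)
from coremf.tables import SampleMetadata, TaxonomyTable


class TestOobMachinery:
    def test_oob_predictions_match_sklearn(self, rng):
        """Our reconstructed OOB aggregation must agree with sklearn's."""
        X = rng.normal(size=(30, 5))
        y = X[:, 0] + rng.normal(0, 0.1, 30)
        rf = RandomForestRegressor(n_estimators=100, oob_score=True,
                                   bootstrap=True, random_state=0, n_jobs=1)
        rf.fit(X, y)
        masks, preds, _ = _forest_oob_state(rf, X)
        counts = masks.sum(axis=0)
        agg = (preds * masks).sum(axis=0) / np.maximum(counts, 1)
        np.testing.assert_allclose(agg[counts > 0],
                                   rf.oob_prediction_[counts > 0], atol=1e-10)


class TestRfImportance:
    def test_true_predictor_ranks_first(self, rng):
        n, p = 40, 50
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"O{j}" for j in range(p)])
        y = X["O0"].to_numpy()
        imp = rf_importance(X, y, n_trees=200, seed=1)
        assert imp.taxon_ids[int(np.argmax(imp.importance))] == "O0"

    def test_duplicated_predictor_pair_stays_top(self, rng):
        n, p = 40, 20
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"O{j}" for j in range(p)])
        X["dup"] = X["O0"]
        y = X["O0"].to_numpy()
        imp = rf_importance(X, y, n_trees=300, seed=2)
        df = imp.to_frame()["inc_mse_pct"]
        assert max(df["O0"], df["dup"]) >= df.drop(["O0", "dup"]).max()

    def test_constant_response_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="constant"):
            rf_importance(X, np.ones(10))

    def test_permutation_p_values_in_unit_interval(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 6)),
                         columns=[f"O{j}" for j in range(6)])
        y = X["O0"].to_numpy() + rng.normal(0, 0.2, 12)
        imp = rf_importance(X, y, n_trees=50, n_permutations=9, seed=3)
        assert np.all((imp.permutation_p > 0) & (imp.permutation_p <= 1))
        assert imp.permutation_p[0] == imp.permutation_p.min()


class TestCoreImportanceContrast:
    @staticmethod
    def _imp(core_vals, other_vals):
        from coremf.drivers import ImportanceResult
        vals = np.concatenate([core_vals, other_vals])
        ids = [f"O{i}" for i in range(len(vals))]
        is_core = np.array([True] * len(core_vals) + [False] * len(other_vals))
        return ImportanceResult(ids, vals, is_core, 1.0, None, 100, 0)

    def test_complete_separation_5v5(self):
        res = compare_core_importance(self._imp([6, 7, 8, 9, 10],
                                                [1, 2, 3, 4, 5]))
        assert res.p_value == pytest.approx(2 / 252)

    def test_identical_values_p_one(self):
        res = compare_core_importance(self._imp([2, 2, 2], [2, 2, 2]))
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_core_importance(self._imp([], [1, 2]))


class TestOlsClusterEmf:
    def test_exact_linear_relation(self):
        ab = pd.DataFrame([[0.0, 1.0, 2.0, 3.0]], index=[1])
        emf = 2.0 * ab.loc[1].to_numpy() + 1.0
        reg = ols_cluster_emf(ab, emf)
        assert reg.table.loc[1, "slope"] == pytest.approx(2.0)
        assert reg.table.loc[1, "r2"] == pytest.approx(1.0)

    def test_r2_equals_squared_pearson(self, rng):
        ab = pd.DataFrame(rng.normal(size=(3, 15)), index=[1, 2, 3])
        emf = rng.normal(size=15)
        reg = ols_cluster_emf(ab, emf)
        for q in (1, 2, 3):
            r = np.corrcoef(ab.loc[q], emf)[0, 1]
            assert reg.table.loc[q, "r2"] == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_cluster_is_na(self):
        ab = pd.DataFrame([[1.0, 1.0, 1.0]], index=[1])
        reg = ols_cluster_emf(ab, np.array([1.0, 2.0, 3.0]))
        assert np.isnan(reg.table.loc[1, "slope"])


class TestTrophicRatio:
    @staticmethod
    def _taxonomy(phyla):
        return TaxonomyTable({f"O{i}": ("Bacteria", p)
                              for i, p in enumerate(phyla)})

    def test_count_basis_arithmetic(self):
        tax = self._taxonomy(["Proteobacteria", "Actinobacteria",
                              "Firmicutes", "Chloroflexi"])
        rep = trophic_ratio(np.array([1, 1, 1, 1]),
                            [f"O{i}" for i in range(4)], tax)
        assert rep.table.loc[1, "ratio"] == pytest.approx(3.0)
        assert rep.table.loc[1, "percent_copiotroph"] == pytest.approx(75.0)

    def test_no_oligotrophs_infinite_ratio(self):
        tax = self._taxonomy(["Proteobacteria", "Firmicutes"])
        rep = trophic_ratio(np.array([1, 1]), ["O0", "O1"], tax)
        assert np.isinf(rep.table.loc[1, "ratio"])
        assert rep.table.loc[1, "percent_copiotroph"] == 100.0

    def test_all_unclassified_errors(self):
        tax = self._taxonomy(["Weirdphylum", "Unknownia"])
        with pytest.raises(ValueError, match="classified"):
            trophic_ratio(np.array([1, 1]), ["O0", "O1"], tax)

    def test_abundance_basis(self):
        tax = self._taxonomy(["Proteobacteria", "Chloroflexi"])
        ab = pd.DataFrame([[0.6, 0.6], [0.2, 0.2]], index=["O0", "O1"])
        rep = trophic_ratio(np.array([1, 1]), ["O0", "O1"], tax,
                            basis="abundance", abundances=ab)
        assert rep.table.loc[1, "ratio"] == pytest.approx(3.0)

    def test_default_map_covers_both_strategies(self):
        strategies = set(DEFAULT_TROPHIC_MAP.values())
        assert strategies == {"copiotroph", "oligotroph"}


class TestZoneComparison:
    def test_separated_cluster_abundance_detected(self):
        samples = [f"S{i}" for i in range(12)]
        zones = ["AL"] * 4 + ["RZ"] * 4 + ["TZ"] * 4
        meta = SampleMetadata(dict(zip(samples, zones)),
                              {s: 1 for s in samples})
        ab = pd.DataFrame([np.r_[np.zeros(4), np.ones(4) * 5, np.ones(4)]],
                          index=[1], columns=samples)
        out = compare_cluster_abundance_by_zone(ab, meta)
        assert out[1].pairwise[("AL", "RZ")].p_value == pytest.approx(2 / 70)
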