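"""Drivers of multifunctionality: random-forest importance of taxa,
cluster-abundance regressions, trophic composition, zone contrasts.

The random-forest importance is the out-of-bag permutation importance
(%IncMSE): the percent increase of the forest's out-of-bag mean squared
error when one predictor is permuted. Only trees that actually split on
the permuted predictor need re-prediction, which keeps the per-predictor
cost proportional to the predictor's usage in the forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils import check_random_state

from .rank_tests import GroupComparison, RankSumResult, compare_groups, rank_sum_test
from .tables import SampleMetadata, TaxonomyTable

logger = logging.getLogger(__name__)

# Phylum-level life-strategy convention (user-overridable): fast-growing
# copiotrophs vs slow-growing oligotrophs.
DEFAULT_TROPHIC_MAP: dict[str, str] = {
    "Proteobacteria": "copiotroph",
    "Actinobacteria": "copiotroph",
    "Bacteroidetes": "copiotroph",
    "Firmicutes": "copiotroph",
    "Acidobacteria": "oligotroph",
    "Chloroflexi": "oligotroph",
    "Planctomycetes": "oligotroph",
    "Verrucomicrobia": "oligotroph",
}


@dataclass
class ImportanceResult:
    taxon_ids: list[str]
    importance: np.ndarray            # %IncMSE per taxon
    is_core: np.ndarray               # bool, aligned to taxon_ids
    oob_mse: float
    permutation_p: np.ndarray | None  # per-taxon p under response permutation
    n_trees: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"otu_id": self.taxon_ids,
                           "inc_mse_pct": self.importance,
                           "is_core": self.is_core})
        if self.permutation_p is not None:
            df["permutation_p"] = self.permutation_p
        return df.set_index("otu_id")


def _oob_masks(rf: RandomForestRegressor, n: int) -> np.ndarray:
    """Out-of-bag masks (tree x sample) for a fitted bootstrap forest.

    Reconstructs each tree's bootstrap draw from its stored random state;
    valid for bootstrap=True with max_samples=None and no sample weights.
    """
    masks = np.ones((len(rf.estimators_), n), dtype=bool)
    for t, est in enumerate(rf.estimators_):
        rng = check_random_state(est.random_state)
        idx = rng.randint(0, n, n)
        masks[t, idx] = False
    return masks


def _forest_oob_state(rf, X: np.ndarray):
    n = X.shape[0]
    masks = _oob_masks(rf, n)
    preds = np.stack([est.predict(X) for est in rf.estimators_])
    feat_to_trees: dict[int, list[int]] = {}
    for t, est in enumerate(rf.estimators_):
        feats = est.tree_.feature
        for f in np.unique(feats[feats >= 0]):
            feat_to_trees.setdefault(int(f), []).append(t)
    return masks, preds, feat_to_trees


def _oob_mse(masks: np.ndarray, preds: np.ndarray, y: np.ndarray) -> float:
    counts = masks.sum(axis=0)
    ok = counts > 0
    agg = (preds * masks).sum(axis=0)[ok] / counts[ok]
    return float(np.mean((agg - y[ok]) ** 2))


def _importances(rf, X: np.ndarray, y: np.ndarray, n_repeats: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, float]:
    n, p = X.shape
    masks, preds, feat_to_trees = _forest_oob_state(rf, X)
    base_mse = _oob_mse(masks, preds, y)
    imp = np.zeros(p)
    for j in range(p):
        trees = feat_to_trees.get(j, [])
        if not trees:
            continue  # predictor never used: permuting it changes nothing
        deltas = []
        for _ in range(n_repeats):
            xp = X.copy()
            xp[:, j] = xp[rng.permutation(n), j]
            preds_j = preds.copy()
            for t in trees:
                preds_j[t] = rf.estimators_[t].predict(xp)
            deltas.append(_oob_mse(masks, preds_j, y) - base_mse)
        imp[j] = 100.0 * np.mean(deltas) / base_mse
    return imp, base_mse


def rf_importance(X: pd.DataFrame, y, core_set=None, n_trees: int = 1000,
                  n_repeats: int = 5, n_permutations: int = 0,
                  seed: int | None = None) -> ImportanceResult:
    """Random-forest %IncMSE importance of taxa for multifunctionality.

    ``X`` is samples x taxa (relative abundances), ``y`` the per-sample
    EMF. ``n_permutations`` > 0 additionally estimates a per-taxon p-value
    by refitting the forest under response permutation (expensive; off by
    default). mtry follows the regression convention of p/3.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.unique(y).size < 2:
        raise ValueError("constant response")
    if n < 8:
        raise ValueError("need at least 8 samples")
    if n < 12:
        logger.warning("random forest fitted on only %d samples", n)
    taxon_ids = list(X.columns)
    core_set = set(core_set or [])
    xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    def fit_and_score(yy: np.ndarray, fit_seed: int):
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=max(1, p // 3),
            bootstrap=True, random_state=fit_seed, n_jobs=1)
        rf.fit(xv, yy)
        return _importances(rf, xv, yy, n_repeats, rng)

    imp, base_mse = fit_and_score(y, int(rng.integers(2**31)))

    perm_p = None
    if n_permutations > 0:
        exceed = np.zeros(p)
        for _ in range(n_permutations):
            y_null = y[rng.permutation(n)]
            null_imp, _ = fit_and_score(y_null, int(rng.integers(2**31)))
            exceed += null_imp >= imp
        perm_p = (1 + exceed) / (1 + n_permutations)

    return ImportanceResult(taxon_ids, imp,
                            np.array([o in core_set for o in taxon_ids]),
                            base_mse, perm_p, n_trees, seed)


def compare_core_importance(imp: ImportanceResult,
                            alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum on %IncMSE, core taxa versus all others."""
    core = imp.importance[imp.is_core]
    other = imp.importance[~imp.is_core]
    if core.size == 0 or other.size == 0:
        raise ValueError("both core and non-core groups must be nonempty")
    return rank_sum_test(core, other, alternative=alternative)


@dataclass
class ClusterEmfRegression:
    table: pd.DataFrame  # index cluster; slope, intercept, r2, p, n

    def row(self, cluster: int) -> pd.Series:
        return self.table.loc[cluster]


def ols_cluster_emf(cluster_abundance: pd.DataFrame, emf) -> ClusterEmfRegression:
    """Per-cluster OLS of EMF on cluster abundance.

    R^2 is the squared Pearson correlation; p is the two-sided t-test on
    the slope. Zero-variance cluster abundances yield NA rows.
    """
    emf = np.asarray(emf, dtype=float)
    if cluster_abundance.shape[1] != emf.size:
        raise ValueError("cluster abundance and EMF sample counts differ")
    if emf.size < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for q in cluster_abundance.index:
        x = cluster_abundance.loc[q].to_numpy(dtype=float)
        if np.std(x) == 0:
            rows.append((q, np.nan, np.nan, np.nan, np.nan, emf.size))
            continue
        res = stats.linregress(x, emf)
        rows.append((q, res.slope, res.intercept, res.rvalue**2, res.pvalue,
                     emf.size))
    return ClusterEmfRegression(pd.DataFrame(
        rows, columns=["cluster", "slope", "intercept", "r2", "p", "n"]
    ).set_index("cluster"))


@dataclass
class TrophicReport:
    table: pd.DataFrame  # index cluster; n_cop, n_olig, ratio, percent_copiotroph
    basis: str


def trophic_ratio(cluster_label: np.ndarray, taxon_ids, taxonomy: TaxonomyTable,
                  trophic_map: dict[str, str] | None = None,
                  basis: str = "count",
                  abundances: pd.DataFrame | None = None) -> TrophicReport:
    """Copiotroph/oligotroph composition of each cluster.

    ``basis="count"`` counts member OTUs per strategy; ``basis="abundance"``
    sums member mean relative abundances (requires ``abundances`` with
    taxa as index). Unclassified phyla are excluded from both the ratio
    and the percentage.
    """
    tmap = DEFAULT_TROPHIC_MAP if trophic_map is None else trophic_map
    if basis not in ("count", "abundance"):
        raise ValueError("basis must be 'count' or 'abundance'")
    if basis == "abundance" and abundances is None:
        raise ValueError("abundance basis requires taxon abundances")
    rows = []
    for q in range(1, int(np.max(cluster_label, initial=0)) + 1):
        members = [o for o, c in zip(taxon_ids, cluster_label) if c == q]
        cop = olig = 0.0
        for o in members:
            strategy = tmap.get(taxonomy.phylum(o), "unclassified")
            if strategy == "unclassified":
                continue
            w = 1.0 if basis == "count" else float(
                abundances.loc[o].mean())
            if strategy == "copiotroph":
                cop += w
            else:
                olig += w
        if cop == 0 and olig == 0:
            raise ValueError(f"cluster {q} has no trophically classified members")
        ratio = np.inf if olig == 0 else cop / olig
        rows.append((q, cop, olig, ratio, 100.0 * cop / (cop + olig)))
    return TrophicReport(pd.DataFrame(
        rows, columns=["cluster", "copiotroph", "oligotroph", "ratio",
                       "percent_copiotroph"]).set_index("cluster"), basis)


def compare_cluster_abundance_by_zone(cluster_abundance: pd.DataFrame,
                                      meta: SampleMetadata
                                      ) -> dict[int, GroupComparison]:
    """Per-cluster Kruskal-Wallis across zones with pairwise Wilcoxon tests."""
    out = {}
    sample_ids = list(cluster_abundance.columns)
    groups = meta.groups(sample_ids)
    if len(groups) < 2:
        raise ValueError("need at least two zones")
    for q in cluster_abundance.index:
        vals = {z: cluster_abundance.loc[q, ss].to_numpy(dtype=float)
                for z, ss in groups.items()}
        out[int(q)] = compare_groups(vals)
    return out
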