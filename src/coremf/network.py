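"""Weighted co-occurrence network: soft threshold, adjacency, topological
overlap, ecological clusters, eigengenes, module membership, hub taxa.

The construction follows the weighted-network recipe used for
co-expression analysis, applied to taxon relative-abundance profiles:

* adjacency ``A_ij = ((1 + cor(x_i, x_j))/2)**beta`` (signed, the default,
  which keeps anti-correlated taxon groups apart) or ``|cor|**beta``
  (unsigned), with ``beta`` chosen as the smallest
  candidate power whose connectivity distribution satisfies the
  scale-free topology criterion (fit R^2 >= 0.9 with negative slope);
* topological overlap ``TOM_ij = (L_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij)``
  with ``L_ij = sum_u A_iu A_uj`` over u != i, j and connectivity
  ``k_i = sum_{u != i} A_iu``;
* average-linkage hierarchical clustering of ``1 - TOM`` with an adaptive
  branch cut subject to a minimum cluster size; taxa outside accepted
  branches stay unassigned (label 0);
* a cluster's eigengene is the leading sample-space singular vector of its
  standardized member profiles; module membership kME is the correlation
  of a taxon profile with an eigengene, and members with kME above a
  threshold (0.9) are hub taxa;
* cluster abundance per sample is the mean of member z-scored
  relative-abundance profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .tables import OtuTable, ensure_relative

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    correlation: str = "pearson"          # "pearson" | "spearman"
    network_type: str = "signed"          # "signed" | "unsigned"
    profile_transform: str = "log"        # "log" | "none"
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    target_r2: float = 0.9
    # None -> adaptive: min(20, max(5, n_taxa // 4))
    min_cluster_size: int | None = None
    kme_hub_threshold: float = 0.9
    # candidate cut heights scan merge-height quantiles in this range
    cut_quantile_range: tuple[float, float] = (0.5, 0.98)
    n_cut_candidates: int = 25
    n_degree_bins: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.target_r2 <= 1):
            raise ValueError("target_r2 must be in (0, 1]")
        if not (0 < self.kme_hub_threshold < 1):
            raise ValueError("kme_hub_threshold must be in (0, 1)")
        if any(b < 1 for b in self.candidate_powers):
            raise ValueError("candidate powers must be >= 1")
        if self.profile_transform not in ("log", "none"):
            raise ValueError("profile_transform must be 'log' or 'none'")

    def effective_min_cluster_size(self, n_taxa: int) -> int:
        if self.min_cluster_size is not None:
            return self.min_cluster_size
        return min(20, max(5, n_taxa // 4))


@dataclass
class SoftThresholdReport:
    powers: list[int]
    r2: list[float]
    slope: list[float]
    mean_k: list[float]
    chosen_power: int
    reached_target: bool


@dataclass
class NetworkResult:
    taxon_ids: list[str]
    sample_ids: list[str]
    params: NetworkParams
    threshold_report: SoftThresholdReport
    adjacency: np.ndarray
    tom: np.ndarray
    connectivity: np.ndarray
    cluster_label: np.ndarray             # 1..K by descending size, 0 unassigned
    eigengenes: pd.DataFrame              # samples x clusters
    kme: pd.DataFrame                     # taxa x clusters
    hub_taxa: dict[int, list[str]]
    cluster_abundance: pd.DataFrame       # clusters x samples
    excluded_taxa: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_label.max(initial=0))

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"otu_id": self.taxon_ids,
                             "cluster": self.cluster_label}).set_index("otu_id")


def taxon_profiles(table: OtuTable, subset=None) -> tuple[pd.DataFrame, list[str]]:
    """Relative-abundance profiles (taxa x samples) for a taxon subset.

    Taxa with zero variance across samples are excluded (their correlation
    with anything is undefined); the excluded ids are returned alongside.
    """
    rel = ensure_relative(table)
    ids = list(rel.otu_ids) if subset is None else list(subset)
    sub = rel.subset_taxa(ids)
    var = sub.values.var(axis=1)
    keep = var > 0
    excluded = [o for o, k in zip(ids, keep) if not k]
    if excluded:
        logger.warning("excluding %d constant-profile taxa from the network",
                       len(excluded))
    kept = [o for o, k in zip(ids, keep) if k]
    if not kept:
        raise ValueError("no taxa with variable profiles")
    return pd.DataFrame(sub.values[keep], index=kept,
                        columns=sub.sample_ids), excluded


def _correlation(profiles: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        from scipy.stats import rankdata
        profiles = rankdata(profiles, axis=1)
    c = np.corrcoef(profiles)
    return np.clip(c, -1.0, 1.0)


def adjacency(profiles: np.ndarray, beta: int,
              params: NetworkParams | None = None) -> np.ndarray:
    """Soft-thresholded adjacency from taxon profiles (taxa x samples)."""
    params = params or NetworkParams()
    cor = _correlation(np.asarray(profiles, dtype=float), params.correlation)
    if params.network_type == "signed":
        a = ((1.0 + cor) / 2.0) ** beta
    else:
        a = np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(a: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} A_ij."""
    return a.sum(axis=1) - np.diag(a)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity distribution.

    Bins k into ``n_bins`` equal-occupancy bins, estimates the density in
    each bin (count / (n * width)), and regresses log10(density) on
    log10(mean k). Returns (R^2, slope) where R^2 is the squared Pearson
    correlation of the binned log-log relationship.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        raise ValueError("too few positive connectivities to bin")
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        raise ValueError("degenerate connectivity distribution")
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    ok = counts > 0
    density = counts[ok] / (k.size * widths[ok])
    # mean k per bin
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(widths) - 1)
    mean_k = np.array([k[idx == b].mean() for b in np.nonzero(ok)[0]])
    x = np.log10(mean_k)
    y = np.log10(density)
    if np.unique(x).size < 3:
        return 0.0, 0.0
    r = np.corrcoef(x, y)[0, 1]
    slope = r * y.std() / x.std()
    return float(r * r), float(slope)


def pick_soft_threshold(profiles: np.ndarray,
                        params: NetworkParams | None = None) -> SoftThresholdReport:
    """Choose the soft-threshold power by the scale-free topology criterion.

    The chosen beta is the smallest candidate whose fit reaches
    ``target_r2`` with a negative slope; if none does, the best-fitting
    power is used and a warning is emitted.
    """
    params = params or NetworkParams()
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[1] < 4:
        raise ValueError("need at least 4 samples")
    if profiles.shape[0] < 10:
        raise ValueError("need at least 10 taxa")
    r2s, slopes, mean_ks = [], [], []
    for beta in params.candidate_powers:
        a = adjacency(profiles, beta, params)
        k = connectivity(a)
        if np.allclose(k, 0):
            raise ValueError("all connectivities are zero")
        try:
            r2, slope = scale_free_fit(k, params.n_degree_bins)
        except ValueError:
            r2, slope = 0.0, 0.0
        r2s.append(r2)
        slopes.append(slope)
        mean_ks.append(float(k.mean()))
    chosen = None
    for beta, r2, slope in zip(params.candidate_powers, r2s, slopes):
        if r2 >= params.target_r2 and slope < 0:
            chosen = beta
            break
    reached = chosen is not None
    if not reached:
        neg = [(b, r) for b, r, s in zip(params.candidate_powers, r2s, slopes)
               if s < 0]
        if neg:
            chosen = max(neg, key=lambda t: t[1])[0]
        else:
            chosen = max(zip(params.candidate_powers, r2s), key=lambda t: t[1])[0]
        logger.warning(
            "no candidate power reaches scale-free R^2 >= %.2f; "
            "falling back to beta=%d (best R^2=%.3f)",
            params.target_r2, chosen, max(r2s))
    return SoftThresholdReport(list(params.candidate_powers), r2s, slopes,
                               mean_ks, int(chosen), reached)


def tom(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (L_ij + A_ij) / (min(k_i, k_j) + 1 - A_ij) with
    L_ij = sum_{u != i,j} A_iu A_uj and k_i excluding the diagonal;
    TOM_ii = 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # L_ij = sum_u A_iu A_uj with zero diagonal excludes u=i,j
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(t, 1.0)
    return t


def cluster_modules(tom_matrix: np.ndarray,
                    params: NetworkParams | None = None,
                    taxon_ids=None) -> np.ndarray:
    """Assign cluster labels by average-linkage clustering of 1 - TOM with
    an adaptive branch cut.

    Candidate cut heights (quantiles of the merge heights) are scanned;
    at each cut, branches whose size reaches ``min_cluster_size`` are
    accepted. The cut retained is the one accepting the most branches
    (ties: most taxa assigned, then the lowest cut), which adapts the cut
    level to the dendrogram instead of fixing a single height. Accepted
    branches are numbered 1..K by descending size (ties by smallest member
    index); everything else is labelled 0.
    """
    params = params or NetworkParams()
    n = tom_matrix.shape[0]
    min_size = params.effective_min_cluster_size(n)
    if min_size > n:
        raise ValueError("min_cluster_size exceeds the number of taxa")
    diss = 1.0 - np.asarray(tom_matrix, dtype=float)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(np.clip(diss, 0, None), checks=False),
                method="average")
    heights = z[:, 2]
    lo, hi = params.cut_quantile_range
    cuts = np.unique(np.quantile(heights,
                                 np.linspace(lo, hi, params.n_cut_candidates)))
    best = None  # (n_clusters, n_assigned, -cut) to maximize
    best_raw = None
    for cut in cuts:
        raw = fcluster(z, t=cut, criterion="distance")
        counts = np.bincount(raw)
        accepted = np.nonzero(counts >= min_size)[0]
        score = (accepted.size, int(counts[accepted].sum()), -cut)
        if best is None or score > best:
            best, best_raw = score, raw
    labels = np.zeros(n, dtype=int)
    sizes = []
    for c in np.unique(best_raw):
        members = np.nonzero(best_raw == c)[0]
        if members.size >= min_size:
            sizes.append((members.size, members[0], members))
    sizes.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, _, members) in enumerate(sizes, start=1):
        labels[members] = new_label
    return labels


def module_eigengene(profiles: pd.DataFrame,
                     cluster_label: np.ndarray) -> pd.DataFrame:
    """Leading sample-space component of each cluster's standardized profiles.

    Each member profile is z-scored across samples; the eigengene is the
    first right singular vector of the member x sample matrix, unit norm,
    oriented so the mean correlation with member profiles is non-negative.
    """
    x = profiles.to_numpy(dtype=float)
    samples = list(profiles.columns)
    eig = {}
    for q in range(1, int(cluster_label.max(initial=0)) + 1):
        members = np.nonzero(cluster_label == q)[0]
        if members.size == 0:
            continue
        sub = x[members]
        sub = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1,
                                                                keepdims=True)
        if members.size == 1:
            e = sub[0] / np.linalg.norm(sub[0])
        else:
            _, _, vt = np.linalg.svd(sub, full_matrices=False)
            e = vt[0]
        cors = _profile_correlations(sub, e)
        if cors.mean() < 0:
            e = -e
        eig[q] = e
    return pd.DataFrame(eig, index=samples)


def _profile_correlations(profiles: np.ndarray, v: np.ndarray) -> np.ndarray:
    p = profiles - profiles.mean(axis=1, keepdims=True)
    vv = v - v.mean()
    denom = np.linalg.norm(p, axis=1) * np.linalg.norm(vv)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, p @ vv / denom, 0.0)


def module_membership(profiles: pd.DataFrame,
                      eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: Pearson correlation of each taxon profile with each eigengene."""
    x = profiles.to_numpy(dtype=float)
    out = {}
    for q in eigengenes.columns:
        out[q] = _profile_correlations(x, eigengenes[q].to_numpy())
    return pd.DataFrame(out, index=profiles.index)


def hub_taxa(kme: pd.DataFrame, cluster_label: np.ndarray,
             threshold: float = 0.9) -> dict[int, list[str]]:
    """Members of each cluster whose own-module kME strictly exceeds the
    threshold (kME exactly at the threshold is not a hub)."""
    hubs: dict[int, list[str]] = {}
    ids = list(kme.index)
    for q in kme.columns:
        members = [ids[i] for i in np.nonzero(cluster_label == q)[0]]
        hubs[int(q)] = [o for o in members if kme.at[o, q] > threshold]
    return hubs


def cluster_abundance(profiles: pd.DataFrame,
                      cluster_label: np.ndarray) -> pd.DataFrame:
    """Cluster relative abundance: per-sample mean of member z-scored profiles.

    Members with zero variance across samples are excluded from the mean.
    """
    x = profiles.to_numpy(dtype=float)
    rows = {}
    for q in range(1, int(cluster_label.max(initial=0)) + 1):
        members = np.nonzero(cluster_label == q)[0]
        if members.size == 0:
            continue
        sub = x[members]
        sd = sub.std(axis=1)
        ok = sd > 0
        if not np.all(ok):
            logger.warning("cluster %d: excluding %d zero-variance member(s) "
                           "from cluster abundance", q, int((~ok).sum()))
        sub = sub[ok]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1,
                                                              keepdims=True)
        rows[q] = z.mean(axis=0)
    return pd.DataFrame(rows, index=profiles.columns).T


def transform_profiles(profiles: pd.DataFrame,
                       params: NetworkParams) -> pd.DataFrame:
    """Profile matrix used for all correlation-based steps.

    ``log`` (default) takes log10 after adding half the smallest nonzero
    value as pseudocount; this tempers the compositional coupling between
    dominant taxa that distorts correlations on the raw relative scale.
    """
    if params.profile_transform == "none":
        return profiles
    x = profiles.to_numpy(dtype=float)
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("all-zero profile matrix")
    return pd.DataFrame(np.log10(x + positive.min() / 2.0),
                        index=profiles.index, columns=profiles.columns)


def build_network(table: OtuTable, subset=None,
                  params: NetworkParams | None = None,
                  beta: int | None = None) -> NetworkResult:
    """Run the full network construction on a taxon subset.

    Adjacency, TOM, clustering, eigengenes and kME operate on the
    (by default log-scale) transformed profiles; cluster abundance is
    computed from the raw relative-abundance profiles. ``beta`` overrides
    the scale-free power selection when given.
    """
    params = params or NetworkParams()
    profiles, excluded = taxon_profiles(table, subset)
    corr_profiles = transform_profiles(profiles, params)
    x = corr_profiles.to_numpy(dtype=float)
    report = pick_soft_threshold(x, params)
    if beta is not None:
        report.chosen_power = int(beta)
    a = adjacency(x, report.chosen_power, params)
    t = tom(a)
    labels = cluster_modules(t, params)
    eig = module_eigengene(corr_profiles, labels)
    kme = module_membership(corr_profiles, eig)
    hubs = hub_taxa(kme, labels, params.kme_hub_threshold)
    ca = cluster_abundance(profiles, labels)
    return NetworkResult(
        taxon_ids=list(profiles.index), sample_ids=list(profiles.columns),
        params=params, threshold_report=report, adjacency=a, tom=t,
        connectivity=connectivity(a), cluster_label=labels, eigengenes=eig,
        kme=kme, hub_taxa=hubs, cluster_abundance=ca, excluded_taxa=excluded)


def edge_list(result: NetworkResult, min_weight: float = 0.0) -> pd.DataFrame:
    """Upper-triangle adjacency as an importable (node1, node2, weight) list."""
    ids = result.taxon_ids
    iu = np.triu_indices(len(ids), k=1)
    w = result.adjacency[iu]
    keep = w >= min_weight
    return pd.DataFrame({
        "node1": [ids[i] for i in iu[0][keep]],
        "node2": [ids[j] for j in iu[1][keep]],
        "weight": w[keep],
    })
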