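"""Quantify what drives multifunctionality.

Random-forest %IncMSE importance of every taxon for EMF with a
core-vs-others Wilcoxon contrast; OLS of EMF on cluster abundance;
copiotroph/oligotroph composition per cluster; cluster abundance
compared between zones.
"""

from pathlib import Path

import pandas as pd

from coremf.drivers import (compare_cluster_abundance_by_zone,
                            compare_core_importance, ols_cluster_emf,
                            rf_importance, trophic_ratio)
from coremf.emf import emf_index
from coremf.tables import (ensure_relative, read_function_table,
                           read_otu_table, read_sample_metadata,
                           read_taxonomy_table)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    otu = read_otu_table(ROOT / "data" / "otu_table.tsv")
    tax = read_taxonomy_table(ROOT / "data" / "taxonomy.tsv")
    meta = read_sample_metadata(ROOT / "data" / "metadata.tsv")
    fx = read_function_table(ROOT / "data" / "functions.tsv")
    core_flags = pd.read_csv(ROOT / "core" / "core_assignment.tsv", sep="\t",
                             index_col=0)["is_core"]
    labels = pd.read_csv(ROOT / "network" / "cluster_labels.tsv", sep="\t",
                         index_col=0)["cluster"]
    cluster_ab = pd.read_csv(ROOT / "network" / "cluster_abundance.tsv",
                             sep="\t", index_col=0)

    emf = emf_index(fx)
    outdir = ROOT / "drivers"
    outdir.mkdir(parents=True, exist_ok=True)

    rel = ensure_relative(otu)
    X = rel.to_frame().T.loc[emf.sample_ids]
    X = X.loc[:, X.var(axis=0) > 0]
    core_set = set(core_flags[core_flags].index)
    imp = rf_importance(X, emf.emf, core_set=core_set, n_trees=1000,
                        seed=SEED)
    imp.to_frame().to_csv(outdir / "rf_importance.tsv", sep="\t")
    contrast = compare_core_importance(imp, alternative="greater")
    print(f"core vs non-core %IncMSE (one-sided Wilcoxon): "
          f"p={contrast.p_value:.3g}, median difference "
          f"{contrast.median_diff:+.2f}")

    reg = ols_cluster_emf(cluster_ab, emf.emf)
    reg.table.to_csv(outdir / "cluster_emf_regression.tsv", sep="\t")
    for q in reg.table.index:
        row = reg.table.loc[q]
        print(f"cluster {q} vs EMF: slope={row.slope:+.3f}, "
              f"R^2={row.r2:.2f}, p={row.p:.2g}")

    trophic = trophic_ratio(labels.to_numpy(), list(labels.index), tax)
    trophic.table.to_csv(outdir / "trophic.tsv", sep="\t")
    for q in trophic.table.index:
        row = trophic.table.loc[q]
        print(f"cluster {q}: {row.percent_copiotroph:.1f}% copiotrophs "
              f"(ratio {row.ratio:.2f}, {trophic.basis} basis)")

    zone_tests = compare_cluster_abundance_by_zone(cluster_ab, meta)
    for q, comp in zone_tests.items():
        r = comp.pairwise[("AL", "RZ")]
        means = ", ".join(f"{z}={comp.group_means[z]:+.2f}"
                          for z in comp.groups)
        print(f"cluster {q} abundance by zone ({means}): "
              f"RZ vs AL Wilcoxon p={r.p_value:.4f}")


if __name__ == "__main__":
    main()
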