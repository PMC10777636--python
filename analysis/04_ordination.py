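"""Ordinate the core microbiota community and test zone separation.

Bray-Curtis distances between samples on the core-taxa relative
abundances, PCoA for visualization coordinates, ANOSIM (global and
pairwise between zones) for significance.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from coremf.community import DistanceMatrix, anosim, bray_curtis, pcoa
from coremf.tables import read_otu_table, read_sample_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    core = read_otu_table(ROOT / "core" / "core_subset.tsv", kind="relative_subset")
    meta = read_sample_metadata(ROOT / "data" / "metadata.tsv")

    d = bray_curtis(core)
    res = pcoa(d)
    outdir = ROOT / "ordination"
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(res.coordinates[:, :2], index=d.sample_ids,
                 columns=["PCoA1", "PCoA2"]).to_csv(
        outdir / "pcoa_coordinates.tsv", sep="\t", index_label="sample_id")
    print(f"PCoA axis 1 explains {100 * res.explained[0]:.2f}%, "
          f"axis 2 {100 * res.explained[1]:.2f}% of the variance")

    groups = meta.zone_vector(d.sample_ids)
    glob = anosim(d, groups, n_permutations=9999, seed=SEED)
    print(f"global ANOSIM: R={glob.r:.4f}, p={glob.p:.4f} "
          f"({'exhaustive' if glob.exhaustive else 'sampled'})")
    zones = sorted(set(groups))
    for i, a in enumerate(zones):
        for b in zones[i + 1:]:
            keep = [j for j, z in enumerate(groups) if z in (a, b)]
            sub = DistanceMatrix([d.sample_ids[j] for j in keep],
                                 d.values[np.ix_(keep, keep)])
            r = anosim(sub, [groups[j] for j in keep], n_permutations=9999,
                       seed=SEED)
            print(f"  {a} vs {b}: R={r.r:.4f}, p={r.p:.4f}")


if __name__ == "__main__":
    main()
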