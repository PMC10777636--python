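"""Core-microbiota identification by the dual abundance-occupancy criterion.

A taxon is core when it is simultaneously highly abundant (top decile of
taxa ranked by mean relative abundance across samples, by default) and
ubiquitous (detected in at least 95% of samples). Occupancy is compared
with exact fractions, so with 12 samples a 0.95 threshold requires
presence in all 12 (11/12 < 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import ceil

import numpy as np
import pandas as pd

from .tables import OtuTable, TaxonomyTable, ensure_relative


@dataclass
class CoreAssignment:
    """Per-OTU core/non-core call with the evidence behind it."""

    otu_ids: list[str]
    mean_rel_abundance: np.ndarray
    abundance_rank_fraction: np.ndarray   # rank / n_taxa, in (0, 1]
    occupancy: np.ndarray                 # fraction of samples with presence
    is_core: np.ndarray                   # bool
    top_frac: float
    occ_frac: float

    @property
    def core_set(self) -> set[str]:
        return {o for o, c in zip(self.otu_ids, self.is_core) if c}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "otu_id": self.otu_ids,
            "mean_rel_abundance": self.mean_rel_abundance,
            "abundance_rank_fraction": self.abundance_rank_fraction,
            "occupancy": self.occupancy,
            "is_core": self.is_core,
        }).set_index("otu_id")

    def core_counts_by_kingdom(self, taxonomy: TaxonomyTable) -> dict[str, int]:
        out: dict[str, int] = {}
        for o in sorted(self.core_set):
            k = taxonomy.kingdom(o)
            out[k] = out.get(k, 0) + 1
        return out


def compute_occupancy(table: OtuTable) -> dict[str, Fraction]:
    """Fraction of samples in which each OTU is detected (value > 0).

    Returned as exact rationals so threshold comparisons like
    11/12 >= 0.95 are decided without floating-point slack.
    """
    n = table.n_samples
    present = (table.values > 0).sum(axis=1)
    return {o: Fraction(int(c), n) for o, c in zip(table.otu_ids, present)}


def identify_core(table: OtuTable, top_frac: float = 0.10,
                  occ_frac: float = 0.95) -> CoreAssignment:
    """Apply the abundance (top fraction of ranked taxa) and occupancy filters.

    Ranking is by mean relative abundance across samples, descending; the
    abundance criterion keeps rank <= ceil(top_frac * n_taxa). Ties at the
    rank boundary are all included, which keeps the result independent of
    input order. Counts tables are converted to relative abundance
    internally.
    """
    if table.n_taxa == 0:
        raise ValueError("empty OTU table")
    for name, v in [("top_frac", top_frac), ("occ_frac", occ_frac)]:
        if not (0 < v <= 1):
            raise ValueError(f"{name} must be in (0, 1], got {v}")

    rel = ensure_relative(table)
    mean_ab = rel.values.mean(axis=1)
    n = rel.n_taxa

    # competition ranking: rank of x = 1 + #{y : mean(y) > mean(x)},
    # so tied taxa share the better rank and the boundary keeps all ties
    order_desc = np.sort(mean_ab)[::-1]
    ranks = np.searchsorted(-order_desc, -mean_ab, side="left") + 1
    cutoff_rank = ceil(top_frac * n)
    abundant = ranks <= cutoff_rank

    occ = compute_occupancy(rel)
    occ_frac_exact = Fraction(occ_frac).limit_denominator(10**9)
    ubiquitous = np.array([occ[o] >= occ_frac_exact for o in rel.otu_ids])

    return CoreAssignment(
        otu_ids=list(rel.otu_ids),
        mean_rel_abundance=mean_ab,
        abundance_rank_fraction=ranks / n,
        occupancy=np.array([float(occ[o]) for o in rel.otu_ids]),
        is_core=abundant & ubiquitous,
        top_frac=top_frac,
        occ_frac=occ_frac,
    )
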