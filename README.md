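# coremf

Core soil microbiota, ecosystem multifunctionality, and weighted
co-occurrence network analysis.

`coremf` is a desk-scale reimplementation of the downstream statistics used
to ask whether a soil community's *core* taxa — the taxa that are at once
highly abundant and ubiquitous across samples — drive soil ecosystem
multifunctionality under a zoned field design (abandoned land AL, root
zone RZ, transition zone TZ, four replicates each). It is aimed at
microbial ecologists who have an OTU table, a taxonomy, sample metadata and
a panel of measured soil functions, and want the full chain from core-taxa
identification to network-cluster driver analysis as tested, reproducible
code. Because the original soil-function measurements of such studies are
rarely deposited, the package ships a synthetic-data generator with planted
ground truth, so every stage can be validated by recovery experiments
rather than by eye.

## What it computes

- **Core microbiota** — a taxon is core when its mean relative abundance
  ranks in the top decile of all taxa *and* its occupancy (fraction of
  samples with nonzero abundance) is at least 95%. Occupancy is compared
  with exact rationals, so with 12 samples the 0.95 threshold means
  presence in all 12.
- **Ecosystem multifunctionality (EMF)** — each soil function variable
  (SOC, TN, AN, AP and the enzyme activities UE, CAT, ACP, PPO, POD, INV)
  is screened with Shapiro–Wilk, log- or square-root-transformed when
  needed, min–max standardized to [0, 1]; EMF(s) is the mean of the
  standardized values of sample *s*. Zones are compared with
  Kruskal–Wallis plus pairwise Wilcoxon rank-sum tests that are **exact by
  enumeration** for groups of ≤ 8 (the attainable two-sided floor for
  4-vs-4 is 2/70 ≈ 0.029).
- **Community ordination** — Bray–Curtis distances
  d(u,v) = 1 − 2Σᵢmin(uᵢ,vᵢ)/(Σᵢuᵢ+Σᵢvᵢ) on the core subset, classical
  PCoA (negative eigenvalues dropped from coordinates and the
  explained-variance denominator), and ANOSIM
  R = (r̄_between − r̄_within)/(M/2) with an exhaustively enumerated
  permutation null whenever feasible.
- **Weighted co-occurrence network** — signed soft-threshold adjacency
  A_ij = ((1+cor)/2)^β on log-scale taxon profiles, β chosen by the
  scale-free topology criterion (fit R² ≥ 0.9); topological overlap
  TOM_ij = (L_ij + A_ij)/(min(k_i,k_j) + 1 − A_ij); average-linkage
  clustering of 1 − TOM with an adaptive branch cut subject to a minimum
  cluster size; module eigengenes E_q; module membership
  kME_iq = cor(x_i, E_q) with hub taxa at kME > 0.9; cluster abundance as
  the per-sample mean of member z-scores.
- **Drivers** — random-forest %IncMSE importance of each taxon for EMF
  (out-of-bag permutation importance) with a core-vs-others Wilcoxon
  contrast; per-cluster OLS of EMF on cluster abundance;
  copiotroph/oligotroph composition per cluster from a configurable
  phylum-level map; cluster abundance compared between zones.

## Worked example

The analysis scripts run the whole chain on a simulated dataset
(400 taxa × 12 samples, 40 planted core taxa, five correlated modules,
one module driving and one suppressing the soil functions):

```bash
python analysis/01_simulate.py
python analysis/02_core_taxa.py
python analysis/03_multifunctionality.py
python analysis/04_ordination.py
python analysis/05_network.py
python analysis/06_drivers.py
```

Output of `02_core_taxa.py`:

```
core taxa: 40 of 400 (top 10% by mean relative abundance AND occupancy >= 95%)
by kingdom: {'Bacteria': 40}
planted core recovered exactly: True
```

The dual abundance–occupancy filter returned exactly the 40 planted core
taxa. `05_network.py` and `06_drivers.py` then report:

```
2 ecological clusters, sizes [20, 20], 0 unassigned taxa
...
core vs non-core %IncMSE (one-sided Wilcoxon): p=2.42e-12, median difference +0.38
cluster 1 vs EMF: slope=+0.367, R^2=0.91, p=1.2e-06
cluster 2 vs EMF: slope=-0.286, R^2=0.80, p=8e-05
cluster 1: 75.0% copiotrophs (ratio 3.00, count basis)
cluster 2: 25.0% copiotrophs (ratio 0.33, count basis)
```

The network splits the core taxa into the two planted ecological
clusters; the cluster built around the planted driver module regresses
positively on multifunctionality (R² = 0.91) and is copiotroph-dominated,
the antagonist cluster negatively (R² = 0.80) and oligotroph-dominated,
and core taxa carry significantly more random-forest importance for EMF
than the 360 non-core taxa. With only four replicates per zone the
ordination statistics are noisy seed to seed (this seed gives a weak
ANOSIM; the across-seed mean AL-vs-RZ R is ≈ 0.4), which is exactly the
statistical reality of a 12-sample field design.

The same pipeline runs from a single YAML config via the CLI:

```bash
coremf run --config run.yaml      # or: coremf simulate / core / emf / ordination / network
```

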