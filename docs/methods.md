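# Methods

This note documents the models and procedures implemented in `coremf`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Core-microbiota criterion

A taxon is core when both hold:

1. **Abundance** — its mean relative abundance across samples ranks in
   the top `top_frac` (default 0.10) of taxa. The rank cutoff is
   `ceil(top_frac * n_taxa)` with competition ranking, so taxa tied at
   the boundary are all included and the result is independent of input
   order. "Top 10%" is read as the top decile of ranked taxa, not a
   cumulative-abundance share: it is the only rank-based reading that
   selects a fixed fraction of taxa.
2. **Occupancy** — the fraction of samples with nonzero abundance is at
   least `occ_frac` (default 0.95), compared with exact rationals. With
   12 samples, 11/12 ≈ 0.9167 fails a 0.95 threshold; the criterion
   demands presence in all 12. Users preferring ceiling semantics can
   lower `occ_frac`.

Counts are converted to relative abundance internally; per-sample
rescaling therefore cannot change the core call (tested property).

## Multifunctionality index

The averaging approach: per function, Shapiro–Wilk at α = 0.05 decides
whether to transform; candidates are tried in the order none → log
(requires strictly positive values) → sqrt (non-negative), keeping the
first that reaches p ≥ α, otherwise the admissible transform with the
largest p. Log before sqrt is the conventional order for concentrations
and enzyme activities. Each retained function is min–max standardized,
`(v − min)/(max − min)`; constant functions cannot be scaled and are
excluded with a warning rather than imputed. EMF per sample is the
unweighted mean of the standardized values, hence always in [0, 1], and
is invariant to increasing affine rescaling of any untransformed raw
variable.

Zone comparisons use Kruskal–Wallis globally and pairwise two-sided
Wilcoxon rank-sum tests. For group sizes ≤ 8 the rank-sum null is
enumerated exactly over all C(n₁+n₂, n₁) assignments of the pooled
mid-ranks, which handles ties without approximation; above that the
tie-corrected normal approximation is used. With four replicates per
group the smallest attainable two-sided p is 2/70, so asymptotic tests
would be misleading. Percent changes are reported as
100·(mean_a − mean_b)/mean_b with the second-named group as reference,
in both orderings.

## Ordination and ANOSIM

Bray–Curtis dissimilarity is computed on the core-taxon relative
abundances (scipy's implementation). PCoA is classical metric scaling:
double-center −D²/2, eigendecompose, scale eigenvectors by √λ.
Bray–Curtis matrices are generally non-Euclidean; negative eigenvalues
are dropped from both the coordinates and the explained-variance
denominator (the uncorrected denominator is available by flag). ANOSIM
uses mid-ranks over all n(n−1)/2 pairwise distances,
R = (r̄_between − r̄_within)/(M/2). The permutation null is enumerated
exhaustively whenever the number of distinct label assignments is at
most 20,000 (e.g. all 20 assignments for two groups of three, all 70
for 4+4 two-zone contrasts at study scale); otherwise p =
(1 + #{R_perm ≥ R_obs})/(1 + n_permutations) with a seeded generator,
so p is reproducible bitwise.

## Weighted co-occurrence network

Profiles are the relative abundances of the chosen taxon subset (the
core set by default). All correlation-based steps operate on
log10-transformed profiles with a pseudocount of half the smallest
nonzero value. This choice is deliberate: on the raw relative scale,
compositional closure couples the dominant taxa — when one abundant
group rises, its members' relative abundances saturate and the group's
internal correlations collapse or turn negative — and in recovery
experiments the planted driver module was unresolvable on raw profiles
while the log scale retained its correlation structure.

- **Adjacency**: signed by default, A_ij = ((1 + cor)/2)^β. The signed
  network is the package's own departure from the older unsigned
  convention: the driver and antagonist clusters of interest here are
  strongly anti-correlated, and an unsigned network (|cor|^β) folds them
  into a single cluster — confirmed in simulation, where unsigned
  clustering plateaued at ARI ≈ 0.78 with the two modules merged.
  Unsigned and Spearman variants remain available.
- **Soft threshold**: for each candidate power 1–20, connectivity
  k_i = Σ_{j≠i} A_ij is binned into 10 equal-occupancy bins; the fit
  regresses log10(density) on log10(mean k), and the scale-free fit R²
  is the squared correlation with a negative-slope requirement. β is the
  smallest power reaching R² ≥ 0.9; if none does (common for small or
  strongly modular networks), the best-fitting negative-slope power is
  used and a warning is emitted.
- **TOM**: TOM_ij = (L_ij + A_ij)/(min(k_i,k_j) + 1 − A_ij),
  L_ij = Σ_{u≠i,j} A_iu A_uj, diagonal 1. Verified against a triple-loop
  oracle at 1e−12.
- **Clustering**: average-linkage on 1 − TOM. The branch cut is adaptive:
  candidate cut heights (quantiles 0.5–0.98 of the merge heights) are
  scanned and the cut accepting the most branches of at least the
  minimum cluster size is kept (ties broken by taxa assigned, then by
  the lower cut) — a single fixed cut height proved brittle across
  dendrogram shapes. The minimum cluster size defaults to
  min(20, max(5, n/4)): 20 for community-scale networks, relaxed for
  small subnetworks where 20 would be half the node set. Clusters are
  numbered by descending size (ties by smallest member index); taxa in
  no accepted branch are labelled 0.
- **Eigengenes and hubs**: E_q is the leading sample-space singular
  vector of the cluster's z-scored member profiles, unit norm, oriented
  so the mean member correlation is non-negative. kME_iq = cor(x_i, E_q);
  hub taxa satisfy kME > 0.9 strictly (0.9 exactly is not a hub).
- **Cluster abundance**: per sample, the mean of member z-scored
  relative-abundance profiles (zero-variance members excluded). Rows are
  mean-zero by construction, so zone contrasts are on z-score means, not
  percentages.

## Driver analyses

- **Random forest**: regression forest (1000 trees, mtry = ⌊p/3⌋,
  bootstrap) of EMF on taxon relative abundances. Importance is
  out-of-bag permutation %IncMSE: permute one predictor, re-predict only
  the trees that split on it, and measure the relative OOB-MSE increase,
  averaged over 5 permutation repeats. The OOB bootstrap masks are
  reconstructed from each tree's random state and are verified in the
  test suite against the library's own OOB predictions. Optional
  per-taxon p-values refit the forest under response permutation (off by
  default; expensive). The core-vs-others contrast is the exact Wilcoxon
  rank-sum on importance values.
- **Cluster regressions**: per cluster, OLS of EMF on cluster abundance;
  R² is the squared Pearson correlation, p the two-sided slope t-test.
- **Trophic composition**: a configurable phylum → strategy map
  (default: Proteobacteria, Actinobacteria, Bacteroidetes, Firmicutes
  copiotrophic; Acidobacteria, Chloroflexi, Planctomycetes,
  Verrucomicrobia oligotrophic; everything else unclassified — a stated
  convention, not a measurement). Ratios and percentages are computed on
  OTU counts by default, with an abundance-weighted basis available;
  unclassified members are excluded from both.

## Synthetic generator

A log-normal latent-factor compositional model with multinomial read
sampling. Defaults define the study conditions: 3 zones × 4 replicates,
400 taxa, 5 modules of 60 taxa, within-module log-scale correlation 0.8,
40 core taxa drawn alternately from the driver and antagonist modules,
50,000 reads per sample, 10 function variables.

- Module factors f_m(s) ~ N(0,1) per sample; the driver module's factor
  is shifted +1.5 SD and the antagonist's −1.5 SD in the treatment zone
  (RZ). Member log-abundances are √ρ·f_m + √(1−ρ)·noise around a
  taxon baseline; non-module taxa are independent.
- Core taxa get a baseline log-abundance lift of 4.3 (SD 0.25) over the
  non-core baseline N(0, 0.8). These values realize the generator's
  planted-structure contract — the core must rank in the top decile and
  appear in ≥ 95% of samples at the default depth — with margin against
  the RZ suppression of antagonist-module core taxa; smaller lifts
  produced occasional single-sample dropouts.
- Reads are multinomial over softmax-transformed log-abundances, so the
  data are compositional with realistic count noise.
- Functions are linear in the *latent factors*
  (effect·(f_driver − f_antagonist) + noise, affinely mapped to plausible
  positive ranges), not in observed abundances, keeping the planted
  causal direction unambiguous; because the core is drawn from the
  driver/antagonist modules, the functions are driven by core-taxa
  factors by construction.
- Phyla: driver-module taxa are 80% copiotrophic, antagonist-module 80%
  oligotrophic, other bacterial taxa mixed; taxa outside modules are
  fungi, so the taxonomy exercises both kingdoms.
- One global seed fans out to independent substreams (latent factors,
  read sampling, functions, taxonomy), so identical configs are bitwise
  reproducible.

**What the generator does not emulate**: phylogenetic correlation,
sequencing chimeras/contamination, overdispersion beyond multinomial,
spatial autocorrelation between zones, fungal co-occurrence structure,
and any real relationship between taxonomy and function. Passing
recovery tests therefore shows the *methods* behave correctly under the
assumed generating model, not that real soils satisfy that model.

## Problem sizes and statistical reality

Recovery experiments run at the study's own scale (12 samples) wherever
the statistic supports it (core identification, cluster regressions,
random-forest contrast). Module recovery uses 14 replicates per zone
(42 samples): with 12 samples, correlation estimates are too noisy for
stable dendrograms, and the scale-up is reported as such wherever those
numbers appear. With 4 replicates per zone the ordination statistics are
intrinsically noisy: the exact two-sided Wilcoxon floor is 2/70, ANOSIM
R for the RZ contrast averages ≈ 0.4 across seeds but ranges from ≈ 0
to 1. The analysis scripts print whatever their seed produced.

## Numerical conventions and edge cases

- Sample order is canonicalized lexicographically at I/O; every
  downstream matrix inherits it.
- Zeros are exact; pseudocounts appear only where a log is taken and are
  half the smallest nonzero value of the matrix at hand.
- Double normalization is an error, not a no-op; subsets of relative
  tables are marked `relative_subset` and never renormalized silently.
- Degenerate inputs (all-zero samples, constant functions, zero-variance
  profiles, clusters of one) are excluded with warnings or raised as
  typed errors as documented per function; nothing is silently imputed.
- Permutation p-value estimators never return 0; enumerated tests use a
  1e−9 rank-sum slack and 1e−12 ANOSIM slack for floating-point ties.

## Known limitations

- The "tree"-style adaptive cut does not implement the hybrid PAM-like
  assignment of borderline taxa; taxa outside accepted branches stay
  unassigned.
- Module merging by eigengene correlation is not performed.
- The trophic map is a phylum-level convention; finer-grained lifestyle
  assignment is out of scope.
- Per-taxon random-forest p-values use full-forest refits and are
  quadratic in cost; they are off by default.
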