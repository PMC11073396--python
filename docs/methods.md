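# Methods

`assemblage` analyses microbial community succession on plastic substrates
("plastisphere") sampled across lakes, polymer types and colonization
times. This note documents the statistical methods, the synthetic-data
model that provides ground truth for testing, the numerical choices, and
the known limitations.

## Diversity measures

**Richness** is the count of taxa with nonzero reads in a sample; no
rarefaction is applied by default (a seeded rarefaction to a common depth
is available as a pipeline option, `rarefy:` in the run config, default
off, because marker-gene studies are split on whether to rarefy and the
choice should be explicit).

**Faith's phylogenetic diversity** is the total branch length of the
minimal *rooted* subtree spanning a sample's taxa. The root connection is
included deliberately: conventions differ, and the rooted variant is
monotone under taxon addition (a property the test-suite asserts) and
makes the PD of a single taxon equal its root-to-tip path length.

**Bray–Curtis** dissimilarity Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) is computed on raw counts.
**Sørensen** dissimilarity β_SOR = (b+c)/(2a+b+c) on presence/absence
(presence is count > 0; no minimum-abundance filter) is partitioned into
Baselga's turnover component β_sim = min(b,c)/(a+min(b,c)) and the
nestedness-resultant remainder β_SNE = β_SOR − β_sim. The ratio
β_ratio = β_sim/β_SOR classifies the dominant driver of beta diversity:
turnover above 0.5, nestedness below. When a pair has identical incidence
(β_SOR = 0) the ratio is undefined and the pair is dropped from cell
means; when one community is empty we set β_sim = 0 (strict nesting).
Partitioning is pairwise (not multiple-site), averaged over the pairs of
each lake × day cell — i.e. across polymers at one place and time — which
supports per-stage trends; cells with fewer than two samples are skipped
with a warning.

## Assembly-process inference

Every within-group sample pair is classified into one of five ecological
assembly processes by a two-step null-model cascade (the
selection-then-dispersal framework standard in microbial ecology):

1. **βMNTD** — abundance-weighted (by default) mean patristic distance
   from each taxon in one community to its nearest relative in the other,
   0.5·[Σᵢ fᵢ·minⱼ dᵢⱼ + Σⱼ gⱼ·minᵢ dᵢⱼ].
2. **βNTI** — the z-score of observed βMNTD within a null distribution
   obtained by shuffling taxon labels across the pool's tree tips
   (n_null = 999 by default; minimum 99). βNTI > +2 → heterogeneous
   selection; βNTI < −2 → homogeneous selection. Pairs with zero null
   spread are flagged undefined and excluded with a warning.
3. **RCbray** — for pairs not resolved by selection, the observed
   Bray–Curtis value is located within a null of randomly assembled
   communities that preserve each sample's richness (taxon inclusion
   probability ∝ pool occupancy) and total count (abundances filled
   1-per-member then multinomially ∝ pool relative abundance), rescaled to
   [−1, 1] with mid-p tie handling: RC = 2·[(#null < obs) + ½·(#null =
   obs)]/n_null − 1. RC > +0.95 → dispersal limitation; RC < −0.95 →
   homogenizing dispersal; otherwise drift.

Boundary handling is strict on both thresholds: βNTI of exactly ±2 and RC
of exactly ±0.95 fall to the stochastic/drift side.

**Pool scope.** The regional pool is per lake by default (matching
per-lake reporting of assembly processes), with a global option. Every
sample of the scope contributes to the pool — water-community samples
included — while classification can be restricted to plastisphere pairs
(`pair_filter`). This matters: if the pool were built only from
selection-filtered biofilm samples, the taxa that selection *excluded*
would be invisible to the tip-shuffle null and homogeneous selection
would be undetectable in principle.

**Replicate sharing.** Within a group, each null replicate draws one tip
permutation (βNTI) or one null assemblage per sample (RCbray) shared
across all pairs, as picante and related implementations do. Each pair's
marginal null distribution is unchanged; null draws are correlated across
pairs within a replicate, which only affects the joint distribution of
z-scores, not their individual calibration.

Group-level fractions report each process's share of classified pairs,
plus aggregates: deterministic (both selections), homogenizing
(homogeneous selection + homogenizing dispersal) and differentiating
(heterogeneous selection + dispersal limitation).

## Succession statistics

**Time decay.** Pairwise similarity (1 − β_SOR) is regressed on
colonization-time lag |dayᵢ − dayⱼ| within each group, by default as
log₁₀ similarity on log₁₀ lag — the standard distance-decay form — with a
lin–lin option recorded in the output's transform tag. Pairs with zero
similarity or zero lag are excluded from the log fit (no pseudocount; an
arbitrary constant would dominate slopes) and counted in the report. The
turnover rate w is the slope magnitude; the signed slope is retained.
Constant similarity returns slope 0 with R² reported as 0.

**PERMANOVA.** Sequential (Type-I) partitioning of the Gower-centred
squared-distance matrix among an ordered list of factors and pairwise
interactions (McArdle–Anderson), pseudo-F per term against the full-model
residual, p by free permutation of sample labels — restricted within
strata when a stratum column is given (the standard mechanism for nested
designs). When the permutation group is no larger than the requested
count it is enumerated exactly and p is the exact tail proportion;
otherwise p = (b+1)/(m+1). Term order is the caller's; 9,999 permutations
default at the CLI. R² over terms plus residual sums to one by
construction. The one-way case is cross-checked against scikit-bio's
PERMANOVA in the test-suite; the multi-term sequential variant has no
Python reference implementation and is verified against exact enumeration
at small n.

**Mantel.** Correlation (Pearson or Spearman) of the off-diagonal entries
of two distance matrices over the same samples; p by jointly permuting
one matrix's rows and columns, (b+1)/(m+1), two-sided by default.
Environmental distances are Euclidean in z-scored variable space, looked
up per sample via its (lake, day).

**Convergence trend.** Per lake, the mean Bray–Curtis dissimilarity
across polymer types at each day, then an OLS fit of those means against
day. A negative slope is the convergence call: communities on different
polymers growing more alike as the biofilm matures. Missing cells (fewer
than two polymers at a lake × day) are skipped with a warning.

## The synthetic study generator

The generator emulates the field design — 4 lakes × 8 polymers × 5
collection days {3, 7, 15, 30, 60} of pooled pellet samples (one pooled
sample per lake × polymer × day, matching the 160-sample arithmetic) plus
4 lakes × 5 days × 2 water fractions (WP/WF) — with controllable,
testable ecology:

- **Composition.** A mother composition over n_taxa (default 300) is
  drawn Dirichlet(pool_concentration); the default concentration 1.0 is
  the uniform simplex prior, and values below 1 give heavier-tailed
  rank-abundance curves. Lake pools are Dirichlet draws around the mother
  with spread set by `pool_divergence`; a single attractor composition
  (the mature-biofilm community) is shared by all lakes. A plastisphere
  sample's effective composition is the mixture
  (1−m(t))·start(lake, polymer) + m(t)·attractor with m(t) = 1−e^(−κt),
  so `convergence_rate` κ > 0 is cross-lake, cross-polymer convergent
  succession as ground truth and κ = 0 switches it off.
- **Membership.** Who colonizes is drawn without replacement (richness
  Poisson around richness_fraction·n_taxa, default fraction 0.1 — real
  amplicon surveys have per-sample richness well below the regional pool)
  from a log-linear preference field
  (1−m)·(lake field + polymer field) + m·attractor field + successional
  drift, each field i.i.d. normal per taxon scaled by its effect size.
  The successional drift is a Brownian field on the stage clock u = κ·t
  shared by every lake and polymer: communities keep replacing species
  along one successional path, which produces monotone time-decay of
  similarity without re-diverging across polymers. With all effect knobs
  at zero membership is exactly uniform.
- **Assembly regimes** (ground truth for recovery tests; they shape
  plastisphere samples only — water samples are always neutral draws, so
  lake pools retain the full taxon diversity):
  - *neutral*: membership as above, counts filled multinomially from the
    effective composition over the members. In the structureless setting
    (κ = 0, no polymer or lake effects) this is exactly the assembly
    process the Raup–Crick null assumes, making calibration a well-posed
    property.
  - *homogeneous_selection*: membership is drawn (near-)uniformly from
    the tips of the favoured clade — the phylogenetically tightest clade
    with 12–25% of the tips, i.e. selection on a conserved trait — with
    log-weight σ (`selection_strength`, default 6) against outside taxa.
    Each sample establishes its own subset of close relatives; shared
    environments select lineages, not identical membership lists. (If
    membership instead tracked the same dominant taxa everywhere, pairs
    would share taxa whose nearest-neighbour distance is zero under any
    tip shuffle, and the βNTI signal would vanish.)
  - *dispersal_limitation*: each sample occupies a uniformly random
    subset (fraction 0.25 of taxa) with its own spiky Dirichlet(0.15)
    abundances — phylogenetically random membership, but pairs far more
    dissimilar than a common-pool null expects.
- **Environment.** Eleven water-chemistry variables per lake × day as
  ρ·(lake baseline + shared day trend) + (1−ρ)·noise with
  ρ = `env_coupling` (default 0.6), in arbitrary z-scored units.

Everything is deterministic given the design seed; sample totals equal
`sequencing_depth` before zero-taxon pruning.

**What the generator does not emulate:** taxonomic identities and real
rank-abundance shapes, within-sample replicate structure, temporal
autocorrelation beyond the successional drift, compositional count noise
from library-size variation, chimeras/contamination, and any coupling
between the prokaryotic and eukaryotic kingdoms (two kingdoms are two
generator calls with different regimes). Passing recovery tests therefore
demonstrates that the inference machinery detects the encoded mechanisms
at realistic scales, not that real plastisphere data satisfy those
mechanisms.

## Numerical choices and problem sizes

- n_null = 999 for calibration-grade runs; 199 suffices for modal-process
  recovery. NullConfig enforces n_null ≥ 99.
- Null-model calibration checks pool ~3,000 pairs from several
  independent single-lake datasets (40 samples each, n_taxa = 300,
  depth = 2,000): pair-level null statistics are correlated within a
  dataset, so aggregating datasets, not pairs, controls Monte-Carlo
  error.
- Regime recovery uses 20 independent seeds of a full single-lake design
  (40 plastisphere + 10 water samples), n_null = 199.
- Type-I calibration uses 500 replicates of n = 16–20 samples with 199
  permutations; the rejection band 5% ± 2.5 pp reflects binomial error.
- Exact PERMANOVA enumeration activates whenever |permutation group| ≤
  requested permutations (e.g. n = 4 free permutation: 24).
- Degenerate inputs: empty communities, single-level factors, all-zero
  rows/columns, missing branch lengths, and saturated models raise
  informative errors; zero-spread nulls and undefined β_ratios are
  flagged and excluded rather than silently coerced.

## Known limitations

- The RCbray null is approximately, not exactly, calibrated on finite
  datasets: occupancy and pooled relative abundance are estimated from
  the data, and under strongly dominance-skewed pools (mother
  concentration well below 1) the pooled abundance differs systematically
  from per-sample fill weights, inflating the extreme-tail rate to ~8% at
  the nominal 5%. Under the default pool it stays within ±2 pp.
- βNTI's two-sided tail rate under its own null runs slightly below the
  normal-theory 4.6% because null βMNTD distributions are mildly skewed;
  this conservatism is inherent to the z-score formulation.
- Sequential (Type-I) PERMANOVA sums of squares depend on term order, as
  in adonis; the order is the caller's responsibility and is echoed in
  the output.
- Time-decay slopes from the log–log form are not comparable to lin–lin
  slopes; the transform tag records which was fitted. Real-data slope
  values are design-dependent and are not reproduced here.
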