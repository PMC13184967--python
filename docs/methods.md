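# Methods

## The inference problem

Replicated microbial time series (treatment x replicate x timepoint count
tables with a phylogeny over the taxa) leave a central question open: how
much of the observed community turnover is deterministic environmental
filtering, and how much is stochastic — dispersal history, or drift?  This
package implements the two-step null-model framework that has become
standard in microbial ecology, together with the surrounding machinery
(ordination statistics, abundant/rare subcommunity stratification,
indicator species, time-lagged association networks) and a synthetic
community generator that plants known assembly regimes so every stage can
be verified end to end.

## Null-model process partitioning

For each pair of communities:

1. **βMNTD / βNTI.**  βMNTD is the abundance-weighted mean patristic
   distance from each taxon present in one community to its nearest taxon
   present in the other (shared taxa are their own nearest neighbours at
   distance zero, the standard `comdistnt` convention).  The null shuffles
   taxon identities across the patristic distance matrix — all pool taxa,
   one permutation per replicate, abundances untouched — and
   βNTI = (βMNTD_obs − mean_null) / sd_null.  βNTI < −2 is homogeneous
   selection, βNTI > +2 variable selection; the inequalities are strict
   and ±2 exactly falls through to step 2.  Pairs whose null distribution
   has zero spread are reported missing (NaN), never ±∞.
2. **RC_bray.**  For the remaining pairs, each null replicate rebuilds
   both communities at their observed richness (taxa drawn without
   replacement with probability ∝ occurrence frequency across the
   regional pool) and observed read totals (multinomial ∝ regional
   relative abundance over the drawn taxa), on integer counts.
   RC = 2·([null BC < obs] + ½[null BC = obs])/n_null − 1; ties are
   half-weighted to avoid bias at exact-equality boundaries (Bray–Curtis
   values are rounded to 12 decimals before comparison so that genuinely
   identical integer configurations tie exactly).  RC > +0.95 is dispersal
   limitation, RC < −0.95 homogenizing dispersal, anything between is
   undominated (drift); again strict inequalities.

Defaults: 999 null replicates for both models (the convention of the
framework; the count is configurable), independent child seeds for the
βNTI and RC stages.  The regional pool for RC is the analysis set actually
passed in, so a per-comparison-class pool is obtained by subsetting before
the call.  Pairs are time-matched by default (within-replicate pairs:
same treatment and timepoint, different replicate; between-treatment
pairs: different treatment, same timepoint); an all-pairs mode exists
because pooled global tables cannot always be attributed to one timepoint.

Subcommunity analyses (abundant > 1%, rare < 0.1% mean TSS relative
abundance, strict thresholds, 0.1–1% intermediate) re-run the full
machinery on the subsetted integer counts with relative abundances
recomputed within the subset — each column of a partition table is a
self-contained analysis.

**SES.MPD** uses the abundance-weighted mean pairwise patristic distance
within a sample against the same taxa-shuffle null.  A sample containing
every pool taxon is invariant under the shuffle; its deviation is exactly
zero and is reported as 0 rather than NaN (0/0 with a zero numerator).

## Community structure statistics

Bray–Curtis is applied to the values as given (TSS proportions for the
standard workflow; raw integer counts inside the RC null).  UPGMA uses
size-weighted average linkage with node heights at half the inter-cluster
mean distance, so ultrametric inputs are reproduced exactly.  nMDS is
SMACOF-based (scikit-learn, non-metric, normalised stress-1, 20 restarts
by default, seeded); PCoA (scikit-bio) is the deterministic alternative
and the one the pipeline uses by default.  PERMDISP embeds samples by
PCoA (positive-eigenvalue axes), measures each sample's distance to its
group's spatial median (Weiszfeld algorithm; centroid by flag) and tests
the one-way F by group-label permutation.  ANOSIM is delegated to
scikit-bio.  Procrustes m² is the normalised residual after optimal
translation/scaling/rotation (scipy), with a PROTEST row-permutation
test.  All permutation p-values use (1 + #(perm ≥ obs))/(1 + n_perm), so
p is never zero and lies on the permutation grid.

Community overlap between replicates is defined as 1 − Bray–Curtis, and
the trajectory distance of a treatment is the Euclidean distance between
its per-timepoint replicate centroid and its first-timepoint centroid in
ordination space.  Both are reasonable defaults for quantities whose
original definitions are not fully specified in the primary literature;
both are configurable.

## Indicator species (IndVal)

Specificity A (share of a taxon's across-group mean relative abundance in
the focal group), fidelity B (occurrence fraction within the group),
IndVal = A·B on the 0–1 scale, each taxon reported for its argmax group
(classic Dufrêne–Legendre; all groups by flag).  Significance permutes
sample-to-group labels and compares the permuted maximum IndVal per taxon.
The screening rule is strict: IndVal > 0.5 AND raw p < 0.05.  No
multiplicity correction is applied to the screen, but BH q-values are
emitted alongside.

## Local similarity analysis (eLSA-style)

Series are normal-score transformed (mid-ranked ties, centred, unit
variance), which makes the score invariant to monotone marginal
transforms.  The local similarity score is the maximal-magnitude
contiguous run of aligned products over all offsets |d| ≤ 3 (positive
delay = second series lags the first), divided by the series length.  The
run search operates on prefix sums (max/min prefix-sum differences); this
is floating-point-identical to exhaustive enumeration over all
(delay, start, end) triples, which the tests exploit as an exact oracle.
Ties break toward the positive sign, then the smaller |delay|, then the
earlier start.  Significance permutes one series' time order (p on the
permutation grid, 1000 permutations by default).

Networks are built per treatment from replicate-averaged relative
abundance trajectories (per-replicate mode available), over taxa present
in ≥ 25% of timepoints — LSA on near-zero series is dominated by ties —
with BH FDR across all tested pairs and edges kept at q ≤ 0.05.  With
1000 permutations the smallest attainable p is 1/1001, so BH can only
reach q ≤ 0.05 when the tested-pair count times 1/1001 divided by the
discovery count stays below the threshold; the prevalence floor is what
keeps real (long-tailed) datasets inside that regime.  Edge scope is
"global" when the full-series association is significant, "local only"
when only sliding windows (length 10, step 1, BH within the window batch)
reach significance.

## Synthetic communities with known assembly regimes

The generator provides ground truth for everything above.  Its backbone:

- **Tree and traits.**  A pure-birth tree (dendropy) with a Brownian
  trait evolved along branches; with rate 0 every tip carries the root
  value.  Default design mirrors a dense succession experiment: 6
  treatments x 3 replicates x 29 twice-daily timepoints, 150 pool taxa,
  2000 reads per sample, lognormal(σ=1.5) rank abundances for a realistic
  rare tail.
- **Clade-level selection.**  The tree is cut into ancestral clades
  (roughly one per six tips, splitting the oldest lineage first); each
  clade carries the mean Brownian trait of its tips, and a Gaussian
  kernel on clade traits (width 0.35 x the clade-trait sd by default)
  decides which clades an environment favours.  Clades are admitted in
  order of trait proximity to the optimum — skipping clades of fewer
  than three tips, which cannot supply co-occurring close relatives —
  until the admitted pool reaches about a quarter of the taxa; a kernel
  that does not discriminate (every clade within 2σ) excludes nothing.
  The budget models competitive exclusion of marginal clades and, more
  practically, keeps per-sample occupancy sparse relative to the pool,
  which the nearest-taxon statistic needs for power.  Two
  empirical facts force this design.  First, tip-level trait windows
  select convergent tips scattered across the tree (their mean pairwise
  patristic distance is indistinguishable from the pool average), so the
  "selected" set is not phylogenetically clustered and βNTI cannot
  respond.  Second, i.i.d. multinomial replicates at realistic depth
  share nearly all taxa, and shared taxa contribute zero to βMNTD under
  both the observed and the shuffled matrix — the observed and null
  statistics coincide.  Detectable homogeneous selection requires
  replicates that share *clades but not taxa*; hence the per-sample
  colonisation lottery (Bernoulli thinning, p = 0.4), a mild lognormal
  abundance jitter (σ = 0.5), and a flattened pool exponent (0.25) under
  selection — favoured taxa bloom toward comparable abundances, which
  keeps the effective number of independent taxa in the weighted βMNTD
  high.  With these choices all five regimes are recovered as the modal
  process downstream.
- **Regimes.**  Homogeneous selection: one shared optimum (0.8 clade-trait
  quantile) for every treatment.  Variable selection: optima at evenly
  spaced clade-trait quantiles (0.1–0.9).  Dispersal limitation: a uniform
  random partition of the pool among replicates (plus a configurable
  shared fraction), each replicate then propagating its own previous
  composition — a random partition spreads every replicate across the
  whole tree, so divergence is taxonomic (RC → +1) without being
  phylogenetic (βNTI ≈ 0); a phylogenetically *stratified* (round-robin)
  partition was rejected because giving every taxon its sister in the
  other replicate depresses βNTI toward the selection zone.  Homogenizing
  dispersal: unselective draws with compositions mixed toward the
  replicate mean (rate 0.7) after each timepoint.  Drift: serial
  multinomial resampling of each replicate's own previous composition
  (Wright–Fisher style).
- **Planted couplings.**  A follower taxon's relative-abundance
  trajectory is overwritten with the driver's, shifted by the lag (held
  at the first value before it), reflected as (max+min) − x for negative
  couplings (an exact negative-linear transform), optionally noised, and
  re-quantised by deterministic largest-remainder rounding that preserves
  each sample's exact read total.  Multinomial re-quantisation was
  rejected: at realistic per-taxon depths it adds 10–20% coefficient of
  variation, which destroys the planted signal the harness exists to
  provide.  Optional window bounds restrict a coupling to part of the
  series (for "local only" scope tests).

What the generator does **not** emulate: mechanistic resource dynamics
(no Monod growth, substrate depletion or metabolite cross-feeding),
compositional sequencing artefacts beyond multinomial resampling, copy-
number variation, or chimeras/contamination.  Passing recovery tests
therefore demonstrates that the statistical machinery identifies the
processes it claims to identify under its own generative assumptions —
not that any particular empirical dataset was assembled by those
processes.

## Reproducibility and numerics

All randomness flows from one master seed through named child seeds
(`crc32(stage) XOR (master·2654435761) mod 2³¹`), so any stage can be
re-run in isolation; every output table carries the package version,
configuration hash and stage seed in a comment line, and two pipeline
runs with the same configuration are byte-identical.  Validation runs
use scaled problem sizes — 150-taxon pools, 10-timepoint series, 999
nulls, 5 scenario seeds for regime recovery; 8 pooled replicate worlds
for the βNTI calibration (pairs sharing one tree and sample set are
strongly correlated, so a single world's grand mean is noisy) — chosen
so the whole validation suite completes in minutes on one core.

Degenerate inputs: zero-sum samples are rejected at load; all-zero taxa
are kept but flagged; constant series standardise to zeros with a
warning; single-taxon samples yield missing SES.MPD; Margalef richness is
0 at N = 1 by convention; empty partition groups are omitted with a
warning.

## Known limitations

- βNTI loses power as per-sample richness approaches the pool size
  (occupancy saturates the nearest-taxon statistic) and as abundance
  distributions become extremely uneven (the weighted mean degenerates to
  a few taxa); the generator's defaults sit in the detectable regime, and
  analyses of real data with very small pools should expect attenuated
  z-scores.
- RC_bray derives its occurrence and abundance weights from the analysis
  set itself; with few samples those estimates are noisy and the null is
  slightly overdispersed.
- The LSA permutation floor of 1/(n_perm+1) bounds the discoveries BH can
  certify; very dense candidate sets need more permutations or a stricter
  prevalence floor.
- Serial-resampling drift couples all taxa through compositional closure,
  so association networks built on drifting communities report genuine
  compositional correlations; the planted-coupling benchmarks use i.i.d.
  draws for that reason.
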