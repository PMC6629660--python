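# Methods

## Model

`syssvm` frames per-patient cancer-gene prioritization as novelty detection.
The positive class — genes with an established role in cancer — is well
curated; a negative class ("genes certainly irrelevant to this tumor") is
not observable. Four one-class SVMs (linear, radial, sigmoid, polynomial
kernels; scikit-learn's `OneClassSVM`) are therefore trained exclusively on
the feature vectors of known cancer genes, and every other damaged
(sample, gene) pair is scored by its similarity to that training cloud.

The unit of analysis is the (sample, gene) pair, not the gene: a gene
damaged in eight patients contributes eight vectors that differ in their
molecular features (alteration counts, copy number, mutation burden) while
sharing their systems-level features. Training uses all vectors whose gene
is in the known-cancer-gene list.

### Cross-validation and best-model selection

Hyperparameters are tuned by iterated cross-validation. One iteration splits
the known cancer genes (by gene, so a gene's vectors never straddle the
split) into ceil(2n/3) training and the remaining test genes; each grid
configuration is fitted on the training vectors and scored by sensitivity,
the fraction of test-gene vectors predicted as members. Sensitivity is
computed at the vector level: each damaged occurrence of a held-out gene
counts once. (An alternative gene-level aggregation would need an arbitrary
voting rule; the vector-level definition is parameter-free.)

Selection is checkpointed: after every `checkpoint_every` iterations (100 by
default) the configuration per kernel with the highest median sensitivity
over all iterations seen so far is frozen; ties are broken by minimum
variance, then by grid order. The walk is repeated `repeats` times (5) over
seeded random re-orderings of the iterations, giving
`repeats * n_iter / checkpoint_every` best-model sets. Early checkpoints see
few iterations and are noisy by design — that diversity is the point of the
ensemble; stable problems collapse onto few distinct configurations.

Default grid: nu in {0.01, 0.05, 0.1, 0.2, 0.3}; gamma in five log-spaced
values from 1e-4 to 1; degree in {2, 3, 4}; coef0 in {0, 1} (230
configurations). A 12-configuration "small" grid serves desk-scale runs.
Both are config-selectable and overridable.

### Scoring and consensus

Each best-model set trains its four kernels on the full known-gene vector
set and computes decision values for every prediction vector. Decision
values of different kernels live on incomparable scales, so each kernel's
values are reduced to cohort-wide percentiles (average rank / n, a
scale-free, rank-preserving transform bounded in [0, 1]); the combined score
is the mean of the four percentiles. Genes are ranked 1..n within each
sample by descending combined score, ties broken lexicographically by gene
id so that ranks are always a permutation. Genes not expressed in the
reference normal tissue (expression <= 0 by default) are removed before
ranking; genes missing from the expression table are removed and logged.

The per-sample top-k genes (k = 10 by default; 5 and 15 supported via
config) form the cohort-level helper candidate list of one best-model set.
Lists are compared by set equality across all sets; the modal list is the
final prediction and its frequency the headline robustness measure. A tie
for the modal position is an error demanding manual resolution, never a
silent pick. The intersection of all lists (the shared core) is also
reported.

### Recursive feature elimination

Per kernel, the model is refitted on the surviving features; the weight
vector w = dual_coef · support_vectors (exact for the linear kernel, the
same formula applied as the stated approximation for the others) is
computed, and the feature with the smallest w² is removed — 34 rounds until
all features are ranked. First removed = least important (rank 34).

## Alteration annotation

- Truncating consequences (stopgain, stoploss, frameshift) are always
  damaging. Missense-like variants (nonsynonymous, nonframeshift) are
  damaging at >=5 of 7 function-based or >=2 of 3 conservation-based
  predictor votes; splicing variants at >=1 of 2 ensemble votes. Silent
  variants are never damaging but count toward the total exonic burden.
  A variant lacking the call group its consequence requires raises an
  explicit error — missing annotation must never silently pass as benign.
- Variants with VAF < 10% and indels longer than 5 bp are removed upstream.
  The VAF/indel filter can be disabled per cohort via config, since its
  applicability differs between primary and validation dialects.
- Copy number supports two dialects: log-ratio segment means
  (CN = 2·2^mean, mean capped at 1.5 against hypersegmentation; amplified /
  deleted called at > 0.3 / < −0.3 on the raw mean) and absolute copy
  numbers. A gene takes a segment's CN when >= 25% of its length is covered;
  among several qualifying segments the largest overlap wins, then the most
  extreme CN, then the leftmost segment — deterministic and independent of
  input order. Coordinates are 0-based half-open throughout.
- Gains are ploidy-corrected: a gene is gained iff its assigned CN exceeds
  the sample ploidy (plus a configurable margin, default 0). A homozygous
  loss is CN <= `hom_loss_max` (default 0; up to 0.5 tolerated for
  fractional CN estimates). Gains, homozygous losses and structural variants
  are always damaging.
- Profiles carry eight damaging-category counts; splicing-damaging events
  are counted in the non-truncating damaging column, which keeps the
  molecular feature count at ten (eight categories + burden + copy number).

## Feature schema

The 34-column schema is a versioned artifact, not hard-coded. The default
encodes 10 molecular features plus 24 systems-level columns: six continuous
properties (gene length, domain count, PPI degree, PPI betweenness, miRNA
count, expression breadth over 30 tissues), three booleans (duplicated,
ohnolog, PPI hub), an 8-level chromatin state one-hot and a 7-age-class
evolutionary origin one-hot. One-hot columns count toward the 34. Missing
systems-level values are imputed with the group median (continuous) or
group mode (categorical/boolean; ties broken lexicographically), the groups
being known cancer genes versus the rest of the mutated genes. Imputation is
idempotent, and a group with no observed value for a property is a hard
error. Imputation precedes scaling.

Scaling is z-scoring with the population (ddof = 0) standard deviation.
Zero-variance columns scale to all zeros with a warning. Scaling statistics
are persisted with the trained model and re-applied verbatim to validation
cohorts — scoring a new cohort must not silently re-standardize it.

## Pathway clustering

Gene-set collections are filtered to sets of 10–500 genes outside hierarchy
levels 1–2 (the level filter is skipped with a warning when no hierarchy is
supplied), with the universe recomputed as the union of retained sets.
Enrichment is the exact one-sided hypergeometric upper tail with
Benjamini–Hochberg correction (enriched at FDR < 0.01 by default). A
sample's perturbation profile P_i is the set of enriched pathways containing
at least one of its altered genes — membership, not leading-edge driving; a
stricter variant would require the altered gene to be among those producing
the enrichment, but the membership reading matches how profiles are mapped
back to patients.

Pairwise similarity is the Jaccard index of profiles; two empty profiles get
similarity 0 (two unperturbed patients share nothing). Clustering is
complete linkage on Euclidean distances between rows of the similarity
matrix — the rows, not 1−J directly, so each sample is represented by its
similarity fingerprint to the whole cohort. The cluster count k maximizes
the median per-sample silhouette over k = 3..20 (truncated to n−1 when the
cohort is small), ties to the smallest k. Cluster–covariate associations are
one-vs-rest: per-level 2x2 Fisher tests for categorical covariates,
two-sided rank-sum for continuous ones, BH-corrected across all tests.

## Germline cascade

Four filters in order, each attaching a machine-readable drop reason and
none mutating its input:

1. **VAF plausibility.** Heterozygous calls are dropped when
   |VAF − 0.5| > 2.6·sd. The standard deviation is modelled as the binomial
   sd at the heterozygous expectation, sd = √(0.25/depth) — depth-aware and
   parameter-free; a cohort-empirical sd can be supplied via config.
   Homozygous calls are dropped below 95% VAF.
2. **Cohort-MAF inflation.** Dropped when cohort MAF > 10% *and* above
   √(10·MAF_reference) against either reference panel (missing reference
   MAFs count as 0).
3. **Heterozygosity excess.** Dropped when the site's heterozygote
   proportion exceeds 1.04 − √(1.04 − 3.74·p_A·p_a), a Hardy–Weinberg-
   motivated bound with empirically chosen constants treated as opaque. The
   radicand is mathematically positive on [0, 0.5]² but clipped at 0
   defensively. Variants without site statistics skip this filter.
4. **Rare damaging retention.** Kept only if damaging — truncating, or >=5/7
   functional votes (no conservation arm in the germline rule) — and with
   MAF < 1% in *both* reference panels. Patients with a retained variant in
   a predisposition gene are flagged.

All inequalities are strict, exactly as written; boundary values survive.

## Expression quantification

FPKM = count / ((library/1e6)·(length/1e3)); gene lengths are inputs
(non-overlapping exonic base pairs), since deriving them from annotation is
upstream of this package. The amplified-vs-neutral comparison pools all
amplified and neutral (sample, gene) expression values into one two-sided
rank-sum test by default, with a per-gene mode that skips genes lacking both
groups. qPCR: r = e − c on the cycle scale and fc = 2^(r_control − r).

## Synthetic cohorts

The generator's defaults are the package's study conditions: 50 patients,
2,000 genes, 50 known cancer genes plus 50 planted helpers drawn from
shifted property distributions, Poisson(80) damaged genes per patient, a 3x
recurrence weight for cancer-like genes, and gain-biased alteration types
for cancer-like genes (gain fraction 0.55 vs 0.20), mirroring a
gain-dominated adenocarcinoma cohort. Real cohorts show a median of a few
hundred damaged genes per patient out of ~17,000; at a 2,000-gene desk-scale
universe the Poisson(80) burden keeps per-patient ranking a meaningful task
(choose 10 of ~80) at the same order of per-gene damage probability.

Cancer-like genes are shifted by `feature_shift` (default 1) standard
deviations on the six continuous properties and separated on booleans and
evolutionary origin through planted-vs-background probability tables —
longer, domain-richer, higher-degree hub genes with broader expression,
ohnolog retention and older origin, the profile reported for cancer genes.
Chromatin state differs only mildly. Five percent of each fallible property
is masked to exercise imputation; length, duplication and ohnolog status are
complete, as in real annotation.

Pathway structure plants patient clusters: each of 40 pathways is assigned
to one of 3 clusters, and a patient perturbs a pathway of its own cluster
with probability 0.85 and foreign pathways with probability 0.02.
`generate_block_profiles` emits the same block structure directly at the
profile level for clustering tests. Germline tables mix Hardy–Weinberg-
consistent sites with planted VAF outliers (~10% of heterozygous calls),
cohort-inflated sites (~8%), heterozygosity-excess sites (~7%) and a rare
damaging tail, a quarter of sites falling in the emitted predisposition-gene
list.

What the synthetic cohorts do **not** emulate: genome coordinates beyond a
synthetic grid, mutational signatures, linkage between neighbouring genes,
read-level noise, correlated systems-level properties, and driver biology —
planted separability is by construction. Passing recovery tests therefore
demonstrates that the machinery ranks what it is pointed at under controlled
signal, not that the feature set distinguishes real drivers; that evidence
must come from real cohorts.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed gives byte-identical outputs end to end, which the test
  suite checks by fingerprinting two full runs.
- Ties are broken deterministically everywhere: grid order and minimum
  variance in model selection, lexicographic gene ids in ranking, first
  index in RFE elimination, smallest k in silhouette selection.
- Percentiles use average ranks, so exactly tied decision values share a
  percentile instead of depending on sort order.
- The scoring-percentile pool is the prediction cohort itself; scores are
  therefore relative within a run and not comparable across cohorts.
- Desk-scale CV (n_iter = 300, checkpoint 100) is the tested configuration;
  the full 10,000-iteration, 500-model-set protocol is the documented
  production setting and differs only in loop counts.
- TSV writers serialize floats with `repr` and readers parse with
  round-trip precision, so write-then-read is an identity (exercised for
  every table type).

## Known limitations

- One interval per gene; overlapping loci or multi-transcript genes must be
  resolved upstream before the 25%-overlap rule.
- The combined-score formula (mean of per-kernel percentiles) is this
  package's documented choice among score-combination schemes; any bounded,
  rank-preserving alternative is config-compatible in principle but not
  implemented.
- No probability calibration: combined scores are relative ranks, not
  membership probabilities.
- Cluster association tests treat covariates marginally; no multivariate
  adjustment.
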