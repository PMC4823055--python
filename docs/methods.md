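# Methods

`adcscreen` implements a three-stage computational screen for
antibody-drug-conjugate (ADC) targets from log2-scale gene expression
matrices: (1) classification of breast samples into molecular subtypes with
an iterative, self-training ensemble; (2) differential-expression filtering
of each subtype against a panel of vital normal tissues; (3) prioritization
and annotation of the survivors — mean-rank ordering, subcellular
localization rules, a subtype-balanced top-50 list, and intersection with
epithelial/mesenchymal marker genes from a cell-line panel. This note
records the models, the defaults and the open design choices.

## Locally adaptive kernel density estimation and the overlap coefficient

The screen's core statistic is the overlapping coefficient of two
densities, OVL = ∫ min(f, g) dx ∈ [0, 1]: a gene whose expression densities
in two sample groups barely overlap is highly discriminative, regardless of
the shape of those densities or the group sizes. Densities are estimated
with an adaptive-bandwidth kernel estimator:

* pilot bandwidth `h = 0.9 · min(sd, IQR/1.34) · n^(−1/5)` (Silverman's
  rule; the sd alone when the IQR vanishes);
* a fixed-bandwidth Gaussian pilot KDE `f̃`;
* Abramson square-root-law local factors `λᵢ = (f̃(xᵢ)/g)^(−1/2)` with `g`
  the geometric mean of `f̃` over the observations (sensitivity exponent
  α = 1/2, configurable);
* `f̂(x) = (1/n) Σᵢ K((x−xᵢ)/(hλᵢ))/(hλᵢ)` with Gaussian `K`.

The adaptive form widens kernels in the distribution tails and sharpens
them near modes, which matters for the skewed, sometimes bimodal intensity
distributions of microarray data. OVL is integrated by the trapezoid rule
on a 512-point grid spanning both samples' supports padded by three maximal
local bandwidths; the same union grid is used for both densities, making
the statistic exactly symmetric in its arguments. Integration error is far
below the sampling noise of the statistic (the estimator's absolute error
against the closed form 2Φ(−δ/2) for unit-variance Gaussians is ~0.01 at
n = 5000).

Zero-spread samples are treated as point masses: two point masses overlap
fully iff they coincide, and a point mass never overlaps a continuous
density. This convention keeps per-gene filters total on constant genes.

Receptor-status imputation uses the same machinery as a two-class
density classifier: `P(pos|x) = π₊f̂₊(x)/(π₊f̂₊(x) + π₋f̂₋(x))` with
class-proportion priors from the annotated samples, ties broken toward
negative. Values outside both supports (both densities numerically zero)
are labelled by the nearest class mean and flagged with a NaN posterior.

## Feature ranking

Three filter statistics rank genes for a binary class contrast:

* **Moderated t with BH q-values.** Per-gene pooled-variance t-statistics
  are stabilised by empirical-Bayes shrinkage: the variance prior
  (d₀, s₀²) is fit by the method of moments on log sample variances
  (matching limma's `fitFDist`, including the infinite-d₀ branch where the
  prior variance is the plain mean of sample variances; verified against
  limma in the test suite). Ranking is by q ascending, ties by |t|.
  Zero-variance genes are excluded from prior estimation.
* **OVL**, ranked ascending (least overlap first), ties broken by |Δmean|
  descending then gene id, so rankings are fully reproducible.
* **|w| of a linear soft-margin SVM** (C = 1) trained on standardized gene
  values, ranked descending.

Feature-set sizes follow the 2^k grid, k = 1…10 for cross-validation and
k = 5…10 for the production ensemble.

## Multiclass decomposition and abstention

Binary experts are combined one-against-one (all class pairs) or
one-against-all. Both use deliberate abstention instead of forced choices:
under OAO a class is assigned only if it wins *all* of its C−1 pairwise
problems (with 4 classes: 3 of 6; with 5: 4 of 10) — at most one class can
do so, which the tests assert by exhaustive enumeration; under OAA a label
requires exactly one positive detector. Accuracy counts abstentions as
errors (configurable), since every attempted sample is a prediction.

## Cross-validation and factor analysis

Accuracy is estimated by repeated (default 10×) stratified 5-fold CV with
feature selection refit inside every training fold, so no test information
leaks into the rankings. For replicated cell-line panels, CV instead splits
*replicate sets*: each line's replicates are randomly assigned to sets, a
subset of sets selects features and trains, and the held-out sets validate,
so no line straddles the train/test boundary. The resulting accuracy table
(one row per feature-selection method × classifier × k × decomposition ×
repeat) feeds a main-effects factorial ANOVA; factors with numerically zero
sums of squares are reported as F = 0, p = 1 rather than 0/0.

## Iterative ensemble self-training

The production classifier is a self-training loop. Each expert —
a (feature-selection method, classifier backend, 2^k) combination — votes
on every sample each iteration; labels winning strictly more than 95% of
non-abstaining votes are fed back as training labels for the next round.
Abstaining experts are excluded from the vote denominator and reported
separately. The loop stops at complete convergence (the labeled assignment
reaches a fixed point), when tier counts are stable for 3 consecutive
iterations, or at `max_iter`. Final confidence tiers: UNANIMOUS (100% of
votes), HIGH (>95%), REASONABLE (>75%), else UNLABELED; final labels are
assigned above the 75% tier.

Seed labels are *eligible for relabeling*: a seed keeps its label until the
ensemble outvotes it above the feedback threshold. This has a practical
consequence for backend choice: classifiers that interpolate their training
set (a linear SVM in 2^k ≥ 32 dimensions, or a fully grown random forest)
hand a mislabeled seed its own wrong label back, splitting the ensemble
vote, whereas smoothing backends (k-nearest-neighbors with k = 5, Gaussian
naive Bayes) vote with the sample's neighborhood and correct it. The
self-training defaults therefore pair kNN and naive Bayes experts with the
moderated-t and OVL rankers; SVM and random-forest backends remain
available (and are the strongest performers in plain CV, where predictions
are always out-of-fold).

Cell-line mode trains every expert once per labeled replicate set and pools
votes per line across its replicates, giving
replicate_sets × unlabeled_replicates × |fs| × |clf| × |k| votes per line
(3 × 3 × 36 = 324 with the full grid).

Classifier backends and their defaults: bagging (10 entropy trees),
entropy-split decision tree, kNN (k = 5, clamped to the training-set size),
Gaussian naive Bayes, random forest (100 trees), linear SVM (C = 1). One
master seed fans out per-repeat/per-expert streams, so any run is exactly
reproducible.

## Target selection

Per subtype, every gene is filtered against each normal tissue:

* per-tissue linear fold `2^(mean_log2_cancer − mean_log2_normal_t)`;
* pass requires max over tissues of the normal/cancer fold ≤ 2, mean over
  tissues of the cancer/normal fold > 2, and mean per-tissue OVL < 0.6.

Ratios are computed in linear space from log2 means (a "ratio of 2" is a
two-fold change); the mean fold is arithmetic by default with a geometric
option, and the OVL clause averages per-tissue coefficients (a pooled
all-normals mode is available). Survivors are ordered by the mean over
tissues of their per-tissue fold-change rank (rank 1 = most overexpressed),
ties broken by gene id.

Localization rules operate on gene-annotation tables: MEMBRANE requires a
protein-coding gene with a plasma-membrane GO term (GO:0005886) or a
"cell membrane" location *and* at least one transmembrane and one
extracellular topological domain; EXTRACELLULAR requires GO:0005576 or an
extracellular-matrix/space/secreted location. A gene may satisfy both rules
and is then eligible for both lists (each list deduplicates internally).

The final list draws genes round-robin across the three subtype orderings
(fixed order luminal → HER2+ → triple-negative, skipping genes already
taken) until 50 genes are collected; with disjoint lists this yields
17/17/16 per subtype. EMT markers come from the cell-line panel with
replicates collapsed to line means: mesenchymal if the mesenchymal/epithelial
fold exceeds 2 with OVL < 0.6, epithelial if the fold is below 0.5 with
OVL < 0.6. All thresholds (2, 0.5, 0.6, 50) are configuration values whose
defaults are the published cut-offs.

Batch structure is assessed two ways: the first two principal components of
the 1,000 highest-total-variance genes, tagged by tissue/status/series; and
per-gene REML variance components from a linear mixed model with tissue and
status fixed and series (experiment) as a random intercept. When the series
variance sits at the zero boundary the REML profile is singular and the
component is reported as 0 with the residual from the fixed-effects fit.

## Synthetic data

The generators produce the statistical structure the pipeline assumes, not
any particular real dataset:

* **Breast cohort** — four classes (normal, luminal, HER2+,
  triple-negative) of equal size; three receptor genes (ESR1, PGR, ERBB2)
  drawn from a two-mode Gaussian (negative mode 4.0, positive mode 10.0,
  sd 0.7 log2 units) according to the sample's true subtype; per-class
  marker blocks (10 genes, +3.0 log2 by default); per-gene baselines
  uniform on [4, 10] with Gaussian noise (sd 1.0); an additive per-series
  shift (5 series, sd 0.3) shared by all genes of a sample; 35% of samples
  with blanked receptor annotations and 5% of seed labels permuted by
  default — the annotation-gap and mislabeling rates the classification
  stage is designed to absorb. Values are clipped to [0, 16].
* **Normal-tissue panel** — 11 tissues (blood, bone marrow, breast, colon,
  heart, kidney, liver, lung, pancreas, skin, stomach) with per-tissue
  baseline offsets; spiked target genes pinned to a chosen (low) mean in
  every tissue.
* **Cell-line panel** — five classes with the 10/23/12/8/6 line split of
  the labeled reference panel, three replicates per line; four gene
  clusters carry the signal, with the epithelial and mesenchymal clusters
  anti-correlated and the mixed class midway.
* **Gene annotations** — membrane/extracellular evidence assigned
  Bernoulli per gene, with decoy near-misses (e.g. a membrane GO term
  without a transmembrane domain) among the rest.

What the generators do *not* emulate: probe-level effects and
normalization artifacts, correlated gene modules beyond the planted
blocks, heavy-tailed noise, class imbalance at real-cohort scale, and
annotation errors beyond uniform blanking/permutation. Passing tests
demonstrate the machinery is correct under its stated assumptions, not
that real cohorts are this separable.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced problem sizes chosen to
exercise every code path with comfortable statistical margins: the
self-training benchmark uses 400 samples × 500 genes with a
2 fs × 2 clf × 3 k grid; target recovery plants 30 membrane genes in a
300-gene universe over 11 tissues; OVL calibration uses n = 5000 per
sample over 20 seeds. Degenerate inputs are handled by explicit
conventions rather than exceptions wherever a filter must stay total
(point-mass OVL, zero-boundary variance components, kNN neighbor
clamping); genuinely unusable inputs (a class with fewer than two labeled
samples, all-identical values where a density is required) raise errors
that name the problem.

## Known limitations

* The OVL estimator is biased upward for very small samples (n < ~10);
  rankings remain usable but absolute coefficients should not be
  interpreted there.
* OAO training uses only the two classes' samples per problem, so a sample
  from a third class is off-manifold for that expert; abstention absorbs
  most, not all, of the resulting noise.
* The mixed model fits one gene at a time and assumes a shared series
  effect across genes of a sample only through the generator, not the
  estimator.
* Self-training can propagate a confident early error; the >95% feedback
  threshold and abstention-aware denominators make this rare on separable
  data but cannot exclude it in principle.
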