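# Methods

## Intragene descriptors

Each gene g with probes β₁,…,β_n ordered by chromosomal coordinate
(MAPINFO) is summarized by five scalars: the arithmetic mean (MEAN),
the sample variance with denominator n−1 (VAR), the mean absolute
consecutive difference (DERIV), the summed absolute deviation from the
chord through the endpoint probes (DEV), and the fraction of total
absolute consecutive variation carried by decreasing steps (ASYMM).
DERIV and DEV use absolute values throughout: without them DERIV
telescopes to (β₁−β_n)/(n−1) — redundant with the endpoints — and DEV
partially cancels, so neither would measure what its name promises.

Genes with fewer than five probes are dropped before any computation:
several descriptors are undefined or unstable below that, and a common
probe floor keeps feature quality comparable across genes. Probes tied
at the same coordinate keep the first occurrence. A gene annotated on
several chromosomes is split into per-chromosome pseudo-genes
(suffix `@<chrom>`), each refiltered at the five-probe floor, because
coordinate arithmetic across chromosomes is meaningless. Degenerate
cases: a constant profile has no directional variation, so its ASYMM is
defined as the neutral 0.5 rather than dropping the gene; DEV's chord
always interpolates the endpoints, so the two endpoint terms are
identically zero.

## Concordance diagnostic

Per sample, the five measures act as judges each ranking the retained
genes (average ranks on ties); Kendall's W with the tie correction
quantifies their agreement. Since every sample ranks the same gene set,
one critical value — from the chi-square approximation χ² = k(m−1)W
with m−1 degrees of freedom at α = 0.05 — applies dataset-wide. The
judges/objects assignment (measures judge genes, per sample) is the
only reading under which a single critical value across samples is
well-defined; it is a design choice, and W here answers "do the five
descriptors order genes interchangeably?" — values above the critical
line with W far from 1 indicate correlated but non-redundant features.
The chi-square approximation is conservative at k = 5 judges (null
rejection near 3% at the nominal 5%), which the calibration test
measures with a Monte Carlo large enough (20,000 replicates) that its
sampling error is small against the tolerance band.

## Classification and error reporting

Two model families estimate class separability on the samples ×
(gene, measure) table under nested 5-fold stratified cross-validation:

- **L1 logistic regression.** Features are z-scored with statistics
  fit on the training part of each fold (the L1 penalty is
  scale-sensitive; unscaled features would make selection arbitrary).
  The inverse regularization strength C is tuned per outer fold by an
  inner 5-fold stratified loop maximizing accuracy over 20 points
  log-spaced on [10⁻³, 10³]; accuracy ties resolve to the smallest C
  (sparsest model). The solver is liblinear. Because liblinear
  penalizes the intercept, the extreme-regularization limit would
  otherwise predict at a decision-value tie; when every coefficient is
  zeroed the model instead predicts the training majority class, the
  natural intercept-only limit of an L1 model.
- **Random forest**, 1000 CART trees of depth 3 by default. Forests
  need no per-fold tuning, so the inner loop is skipped and only the
  outer loop estimates quality.

With the "induced" class designated (default: the lexicographically
last label, so iPSC over ESC), type I error is the fraction of
induced-class samples called the base class, type II the reverse, and
misclassification the total fraction wrong; each is reported as
mean ± sd (ddof = 1) over the outer folds. Fold assignment and model
seeds all derive from a single integer seed, so reports are exactly
reproducible.

## Recursive best-feature elimination

RBFE inverts backwards elimination: at each iteration the base model is
fit on the remaining pool and its *top* batch — by |standardized
coefficient| for the linear model at the inner-loop-selected C, by
impurity importance for the forest, ties broken by feature name — is
moved to the selected set. Three cross-validated error reports are
computed per iteration: on everything selected so far, on the current
batch alone, and on the remaining pool. Default batch sizes are 250
(linear base) and 1000 (forest base), both configurable; fold seeds are
the master seed plus the iteration index so single iterations rerun
independently. The procedure ends when the pool empties (the final
batch takes whatever remains), or earlier if a maximum iteration count
is set — in which case the batches no longer partition the feature set.

Two behaviors of the traces are worth knowing. First, L1's inherent
selection is unstable: the number of nonzero coefficients varies
between folds, and features at zero coefficient are tie-broken by
name, so a single linear-base batch is not guaranteed to capture every
informative feature. The forest base ranks all features densely and is
the reliable choice when batch-level recall matters; a Jaccard-overlap
diagnostic of L1 support sets across folds is provided without an
attached threshold. Second, the error on the remaining pool typically
climbs *above* 0.5 in later iterations: those features have been
selected against on the full data set, which conditions them to be
anti-informative on the held-out folds as well.

## Stump ranking and enrichment

Each gene's single-feature quality is the 5-fold stratified
cross-validated misclassification of a depth-1 decision tree on that
one feature — a transparent importance with the units of an error rate.
The split search is an exact vectorized equivalent of CART's best-gini
midpoint search for a single feature (first minimum on ties; a feature
constant on the training fold predicts the training majority class); it
is cross-checked against scikit-learn's tree on random data in the test
suite. Genes sort best-first (ties by name) and only those with mean
error strictly below 10% are retained; the comparison subtracts 1e-9
from the cutoff so a fold-averaged error that is exactly 10% in exact
arithmetic cannot slip below it through float rounding.

Enrichment scans progressively growing prefixes of the retained list:
for prefix length n with k members of a gene set of size K (after
intersection with the universe of N filtered genes), the p-value is the
upper-tail hypergeometric probability P(X ≥ k). The universe is the
set of genes passing the five-probe filter — the pool classifiers were
actually selected from — not the whole genome. The null is rejected
where p < 0.01 with no multiple-testing correction across prefixes or
sets (a Bonferroni column is emitted for reference but does not gate
the flag). Scanning only the retained genes matters: prefixes over the
full ranking would accumulate thousands of dependent tests and inflate
the family-wise minimum p of even an unrelated decoy set.

## Synthetic data

The generator emulates the shape of a two-group 450K stem-cell study:
genes of 5–20 probes laid consecutively on chromosomes with inter-probe
spacings of 50–500 bp, per-gene baseline means uniform on [0.2, 0.8],
per-probe offsets N(0, 0.05) shared by both classes, per-entry Gaussian
noise (sd 0.05 by default) and clipping to [0, 1]. Default sample sizes
are 31 + 35. Class differences are planted per measure so pipeline
recovery is checkable against ground truth: an additive shift of all
probe means (MEAN), an alternating ±effect/2 zigzag inflating
dispersion (VAR/DERIV), replacement of probe means by a strictly
decreasing linear ramp (ASYMM — chosen because its noise-free limit is
exactly 1), and a triangular mid-gene bump off the endpoint chord
(DEV — closed-form in the noise-free limit). A warning fires if
clipping displaces more than 1% of entries by over three noise sd,
the sign of an effect too large for the beta scale.

What the generator does *not* model — probe-type chemistry differences,
batch effects, beta-valued (rather than clipped-Gaussian) noise, CpG
island structure, correlated effects across genes, somatic-memory
heterogeneity — bounds what passing tests show: they demonstrate that
the pipeline recovers the kind of signal it is designed for at
realistic sample sizes, not that real reprogramming differences take
this form or this effect size.

## Problem sizes and numerical choices

The test and acceptance workloads use 2000 genes (about 25,000 probes)
with 50 planted genes at a MEAN shift of 0.15 over noise sd 0.05 for
classification, recall and enrichment checks; 200 genes with 20 planted
for RBFE traces; and 20 simulation seeds for rate estimates — sizes
chosen so each check completes in minutes on one CPU while keeping the
sample-to-feature ratio of the emulated study. Beta matrices and
measure tables are written with 6 significant digits, and round-trips
are exact at that precision. All stage seeds fan out deterministically
from one master seed via stage-name CRC offsets; reruns with the same
configuration reproduce every tabular artifact byte-for-byte (the JSON
run report additionally records wall-clock timings, which naturally
differ).

## Limitations

Classification errors at 66 samples carry large fold-to-fold standard
deviations; single-fold differences of one sample move an error by
~7 percentage points, so per-measure comparisons should lean on the
reported sd. The Kendall critical value is approximate (conservative)
rather than exact. The hypergeometric prefix scan treats gene ranks as
fixed; it does not account for the selection noise in the stump errors
that produced the ranking. Real-data preprocessing (IDAT parsing,
normalization, probe-type correction) is out of scope — the loader
takes beta values as given.
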