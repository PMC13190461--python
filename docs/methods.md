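# Methods

This note documents the statistical model behind `cohortcv`, the
assumptions and defaults that matter, what the synthetic generator does
and does not emulate, and the numerical choices a maintainer would want to
know about.

## The estimation problem

The package treats supervised learning as a *descriptive* instrument for
small longitudinal cohorts: the quantity of interest is internal
discrimination — how well clinical covariates and genus-level microbiome
composition organize subjects into outcome-concordant groups — not
external predictive performance. Everything in the design follows from two
facts about such cohorts: (i) repeated samples per subject are not
independent, and (ii) with tens of subjects, any data-dependent choice
made outside the training partition biases the estimate upward.

## Pipeline

**Preprocessing (cohort-level, fixed order, logged):** samples with
library size < 3,000 reads are dropped; genera on a curated
reagent-contaminant blocklist (nine genera reported in sequenced negative
controls, plus chloroplast reads) are removed; genera present in < 5% of
samples are removed (threshold inclusive, presence = count > 0). A
frequency-based contaminant score is also provided: for each taxon,
log10 frequency is regressed on log10 DNA concentration under a
contaminant model (slope fixed at −1, free intercept) versus a constant
model, and the RSS ratio is referred to an F(n−1, n−1) tail. Both models
have one free parameter, so this is a ratio diagnostic rather than a
nested-model test; it is deliberately conservative under the null and is
exposed behind a single swappable function.

**CLR transform.** Counts are pseudocounted (default 0.65, on the count
scale) and mapped to ln(x_i/g(x)). A 0.65 offset on the relative-abundance
scale would dominate the data, so the count-scale reading is used; the
sensitivity suite varies the pseudocount over {0.5, 0.65, 1.0}. Two
within-fold modes exist: `per_sample` (the default; each sample divided by
its own geometric mean, so there is no fitted state and no leakage by
construction) and `train_anchored` (the denominator replaced by a constant
derived from the per-taxon mean log counts of training samples, for
replication of training-derived-denominator designs). The modes agree
whenever training samples share one composition; neither is claimed to be
the uniquely correct reading.

**Feature construction.** Microbiome features are the CLR values of
either all filtered genera or the genera selected within the training
fold by the DA test at p < 0.10, plus Shannon diversity (−Σ p ln p,
natural log, computed per sample from untransformed relative abundances —
a per-sample quantity, hence leakage-free). Clinical features follow one
of three strategies: the minimal pair (gestational age at sampling,
maternal age); a fixed ten-variable literature list; or data-driven
screening — Mann–Whitney U for continuous covariates, Fisher's exact test
(exact r×2 enumeration under the point-probability rule) for categorical,
rank by ascending p with alphabetical tie-break, take the top 10, force-
include the mandatory pair. Screening sees one row per subject;
time-varying covariates are reduced to the value at the subject's earliest
sample (the reduction is a convention; nothing downstream depends on it
strongly). Variables missing in ≥ 30% of training subjects are excluded;
missing values are never imputed. A single rank test is used for all
continuous variables (rather than switching between t and rank tests by a
normality check) to keep the screen deterministic; published p-values
produced by a t-test may therefore differ slightly for near-normal
variables.

**Differential abundance stand-in.** Per taxon, ordinary least squares of
CLR value on outcome plus covariates (default: maternal age,
pre-pregnancy BMI); LFC is the outcome coefficient, p its two-sided t
tail, q the Benjamini–Hochberg adjustment. All taxa share one design
matrix, so the fits reduce to a single vectorized solve. This estimator
assumes independent samples; with repeated measures its p-values are
descriptive ranking scores, which is exactly how the within-fold selection
uses them (threshold 0.10, selection tallied across folds). The function
signature is an adapter seam: any callable with the same contract — for
example a wrapper around an external bias-corrected compositional DA tool
— can replace it throughout the pipeline. Published effect sizes from such
tools are consequently not comparison targets for the stand-in.

**Folds.** Subjects are stratified by outcome, shuffled with the seed,
and dealt round-robin from fold 0 per class, so per-fold class counts
differ by at most one and both classes' shortfalls stack on the last
folds: 43 subjects with 14 positives and k = 5 yields sizes 9,9,9,9,7
with positive counts 3,3,3,3,2. If aligned dealing would leave a fold
empty (possible only when n < 2k), the class deals are staggered so every
fold receives a subject. Inner splits are stratified 70/30 at subject
level within each outer training set.

**Threshold freezing.** The inner-train model's inner-validation
subject-level probabilities define a Youden search over the midpoints of
consecutive distinct probabilities plus {0, 1}; ties take the smallest
maximizing threshold (favouring sensitivity). A single-class inner
validation set falls back to 0.5 with a warning. The model is then refit
on the full outer training set (the inner model is discarded) and the
frozen threshold is applied to outer-test subject-level probabilities.
Classification at the threshold uses ≥ (ties classified positive).

**Models.** Random forest: 500 trees, 4 candidate features per split,
`min_samples_split = 10` (the closest scikit-learn analogue of a
minimum-node-size-to-split control), seeded. Elastic net: logistic
regression at α = 0.5, λ = 0.01 on predictors standardized by
training-fold mean/SD; λ of the average-loss objective maps to
C = 1/(n·λ) in scikit-learn's summed-loss objective. Fits warm-start from
the null model (zero coefficients, intercept at the weighted base-rate
logit), the same initialization coordinate-descent implementations use;
this leaves operating-λ solutions unchanged and makes the λ → ∞ limit
(all probabilities equal to the training base rate) numerically
attainable. `mtry` stays at 4 for every configuration even though feature
counts range ~14–70, matching the fixed-a-priori design. Hyperparameters
are never tuned anywhere in the pipeline.

**Weighting (sensitivity only).** Inverse-frequency weighting gives each
training sample weight 1/n, n being its subject's sample count in the
fitting set, so every subject contributes total weight exactly 1.0; an
audit channel records the per-subject sums. The same weighting is used in
the inner fit and the outer refit.

**Metrics.** AUROC by the midrank Mann–Whitney formulation; PRAUC as
average precision (the step-wise integral — interpolation conventions
differ between packages, so the convention is pinned here); positive class
is the adverse outcome. Balanced accuracy is (sensitivity+specificity)/2.
Single-class fold labels make metrics undefined; such folds are recorded
as degenerate and summaries average the remaining folds, with the count
reported.

**Permutation test.** m full pipeline reruns (default 500) on
subject-permuted labels, each with a *fresh* fold plan stratified on the
permuted labels — the observed statistic's fold structure is
label-dependent, so exchangeability requires rebuilding it. The statistic
is the mean outer-fold subject-level AUROC; p = (b+1)/(m+1). Failed
replicates are redrawn (bounded retries), never dropped silently.

**Seeding.** One master seed derives every stream (fold shuffles, model
fits, permutation draws) through SeedSequence keyed by purpose, fold,
configuration and replicate, so any piece is independently replayable and
identical seeds give byte-identical summaries and null vectors.

## Synthetic cohort generator

The generator reproduces the *processed-data structure* the pipeline
assumes: 43 subjects with 14 positives by default; samples per subject
drawn 1 + Poisson(mean − 1) truncated at 6, with group means 3.0 (term)
and 1.7 (preterm) because early delivery interrupts follow-up;
gestational ages drawn by trimester weights (0.427, 0.400, 0.173) and, for
preterm subjects, truncated below a simulated delivery age
(Uniform(32, 36.9), with an optional single 20.0-week outlier to exercise
the exclusion sensitivity); libraries log-normal (median ≈ 30k reads)
floored at 3,000.

Counts are multinomial draws from softmax(state baseline + subject effect
+ outcome × planted LFC + sample noise) over 49 genera. Two community
states: a dominant state whose noise-free expected Lactobacillus share is
0.93 — chosen so the *realized* median dominance under the default noise
(subject-effect SD 1.0, sample-noise SD 0.5, both on the log scale) is
≈ 0.82 — and a dysbiotic state (24% of subjects) spreading mass over five
anaerobe-like genera. The subject effect vector is drawn once per subject
and shared by all its samples; this is the repeated-measures structure
that makes sample-level CV leak, and the generator exposes it through a
ground-truth debug channel. One planted taxon (+1.0 log-fold-change on the
positive class) is the default recoverable microbiome signal. Clinical
covariates are drawn per-group from a configurable spec whose defaults
match the cohort's published contrasts (e.g. wider BMI spread and a 21.4%
membrane-rupture rate under the positive outcome). `null_params()` yields
a fully null cohort — no planted taxa, group-identical covariates,
outcome-independent sampling depth and timing — used for calibration.

What the generator does **not** emulate: phylogenetic correlation between
taxa, batch effects, read-level error, the exact per-subject sample-count
multiset of any real cohort, and real taxon identities (names are
field-typical labels). Realized alpha diversity in the dysbiotic state is
broader than real vaginal communities show. Passing tests therefore
demonstrate that the *machinery* is correct and calibrated under the
assumed structure, not that any real dataset's effect sizes are
recoverable.

## Problem sizes used by the test suite

The behavioural suites run at desk scale, chosen once from timing
benchmarks of the model fits: the leakage battery uses 20 seeds of
43-subject null cohorts with subject-effect SD 2.0 and 30 taxa, comparing
subject-level against (deliberately broken, test-only) sample-level CV by
fold-mean AUROC — threshold-free, so the inner loop is skipped; the
permutation calibration uses 50 seeds × m = 99 with the elastic net on
20-subject, 20-taxon null cohorts at k = 3; DA recovery uses 80 subjects
(~200 samples) with subject-effect SD 0.3, matching the independence
assumption of the per-sample estimator whose precision the ±0.25 band
reflects; the determinism check runs the full 12-cell grid twice on a
24-subject cohort. The reference fold-structure quantities recomputed by
`scripts/acceptance.py` are exact properties of the dealer and hold for
every seed.

## Known limitations

- The DA stand-in ignores within-subject correlation and compositional
  bias correction; its global q-values on real repeated-measures data are
  optimistic and should be treated as ranking scores.
- The elastic-net/λ mapping and standardization mean coefficients are not
  numerically identical to other implementations' at the same nominal λ,
  though the fitted probabilities agree closely at the operating values.
- Degenerate folds (single-class inner validation or test sets) are
  handled by fallback-and-record rather than abort; with very small or
  very imbalanced cohorts the summary may average fewer than k folds.
- `validate_cohort` checks structural invariants, not biological
  plausibility; gestational ages are only range-checked.
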