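# cohortcv

Leakage-aware, subject-level nested cross-validation for small longitudinal
microbiome cohorts with a binary clinical outcome — built for studies like
vaginal-microbiome preterm-birth (PTB) cohorts, where a few dozen
participants each contribute several 16S genus-level samples across
pregnancy, and where naive analysis quietly inflates every performance
number.

## Who this is for, and the problem it solves

Repeated measures leak. Samples from the same participant share host
biology, so any cross-validation that splits *samples* lets the model
memorize participants instead of learning outcome structure; with strong
between-subject variation and zero real signal, sample-level CV can report
AUROC above 0.9 (this package demonstrates that failure mode on purpose).
Small cohorts add further traps: thresholds tuned on test data, feature
selection run before splitting, compositional transforms fitted on the
full dataset.

`cohortcv` packages the defensive design as a reusable pipeline:

- **Subject-level stratified outer folds** (all samples of a participant
  travel together; per-fold case counts balanced to within one).
- **Within-fold preprocessing**: centered log-ratio (CLR) transform with a
  pseudocount, differential-abundance (DA) taxon selection at p < 0.10, and
  clinical covariate screening are all fitted on the training partition
  only.
- **Frozen Youden thresholds**: an inner stratified 70/30 subject split
  picks the cutoff maximizing J = sensitivity + specificity − 1; the
  threshold is frozen before the outer test fold is touched.
- **Subject-level metrics**: sample probabilities are averaged per subject
  before AUROC, PRAUC, sensitivity, specificity and balanced accuracy are
  computed.
- **A 2×3×2 configuration grid**: {random forest, elastic net} ×
  {minimal, literature-based, data-driven clinical features} ×
  {DA-selected taxa, full filtered profile} = 12 cells, with fixed a-priori
  hyperparameters (500 trees, mtry 4, minimum node size 10; α = 0.5,
  λ = 0.01).
- **A subject-level permutation null**: labels shuffled across subjects,
  the whole pipeline rerun per permutation, p = (b+1)/(m+1)
  (conservative; never zero).
- **Stability and sensitivity analyses**: selection frequencies and
  importance ranks across folds; pseudocount, λ, early-sampling,
  outlier-exclusion and inverse-frequency-weighting variants.
- **A synthetic cohort generator** that emulates the data structure
  (43 subjects, 14/43 PTB, 1–6 samples each, Lactobacillus-dominant vs
  dysbiotic community states, subject-shared random effects, planted
  differentially abundant taxa, clinical covariates with realistic group
  contrasts), so everything is testable with no external data.

The core transform is the CLR: for a composition x with D parts,
CLR(x)_i = ln(x_i / g(x)) with g(x) the geometric mean; zeros are handled
by a count-scale pseudocount (default 0.65). The DA step fits, per taxon,
CLR ~ intercept + outcome + covariates by least squares (LFC = the outcome
coefficient, Benjamini–Hochberg q across taxa) and is exposed behind a
pluggable seam so a bias-corrected external DA tool can be substituted.

## Worked example

`examples/02_run_grid.py` generates a synthetic cohort (seed 7: 43
subjects, 14 PTB, 111 samples, 49 genera) and runs the full grid:

```
    algorithm clinical_strategy microbiome_rep  auroc_mean  auroc_sd  prauc_mean  n_folds_ok
random_forest        literature  full_filtered       0.684     0.244       0.602           5
  elastic_net        literature    da_selected       0.662     0.218       0.648           5
  elastic_net       data_driven    da_selected       0.660     0.190       0.619           5
  ...
random_forest     dream_minimal    da_selected       0.367     0.210       0.345           5

best configuration: random_forest/literature/full_filtered
top features by mean importance rank across folds:
           feature  mean_rank  folds_present
  prepregnancy_bmi        3.0              5
   Corynebacterium        3.6              5
             pprom        4.8              5
Peptostreptococcus        6.0              5
```

Each row is one configuration; `auroc_mean ± auroc_sd` is the mean ±
standard deviation of the subject-level AUROC over the 5 outer folds.
Values near 0.5 mean no recoverable outcome structure; the spread across
configurations and the large fold-to-fold SDs are exactly what honest
evaluation on ~43 subjects looks like. The importance table shows that the
planted clinical contrasts (BMI, membrane rupture) and microbial signal
surface consistently across folds. `examples/03_permutation_test.py`
tests one configuration against its permutation null (printing, e.g.,
`observed mean outer-fold AUROC: 0.662 ... p_perm = (6+1)/(49+1) = 0.140`),
and `examples/01_simulate_cohort.py` / `examples/04_sensitivity.py` cover
the generator and the sensitivity variants.

A thin CLI mirrors the library for file-based use:

```bash
cohortcv simulate --seed 7 --out cohort/
cohortcv run --counts cohort/counts.tsv --samples cohort/samples.csv \
             --subjects cohort/subjects.csv --out results/
cohortcv permute --m 500 ... ; cohortcv sensitivity ...
```

## Layout

```
src/cohortcv/
  cohort.py        data model, validation, TSV/CSV I/O
  simulate.py      synthetic cohort generator (+ contaminant planting)
  compositional.py filters, decontamination, CLR, Shannon diversity
  da.py            differential-abundance stand-in, BH, stability tallies
  clinical.py      univariate tests and the three feature strategies
  crossval.py      folds, Youden freezing, models, metrics, the grid
  resampling.py    permutation test, stability report, sensitivity suite
  results.py       result bundles and output formats
  cli.py           thin command-line wrapper
docs/methods.md    model, assumptions, parameter choices, limitations
examples/          one narrative script per capability
```
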