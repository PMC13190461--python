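"""Run the 12-configuration nested cross-validation grid on a synthetic
cohort and print the discrimination summary.

Each configuration is one cell of algorithm (random forest / elastic net)
x clinical strategy (minimal / literature / data-driven) x microbiome
representation (DA-selected taxa / full filtered profile). Metrics are
subject-level, averaged over 5 outer folds; thresholds are frozen on inner
validation splits, so nothing is tuned on test subjects.
"""

from cohortcv import (AnalysisConfig, CohortParams, generate_cohort,
                      preprocess_cohort, run_grid, stability_report)

cohort = generate_cohort(CohortParams(seed=7))
config = AnalysisConfig(seed=7)
filtered, provenance = preprocess_cohort(cohort, config)
for step in provenance:
    print(f"{step['step']}: "
          f"{step.get('taxa_removed', step.get('samples_removed'))}")

grid = run_grid(filtered, config)
cols = ["algorithm", "clinical_strategy", "microbiome_rep",
        "auroc_mean", "auroc_sd", "prauc_mean", "n_folds_ok"]
print(grid.summary[cols].round(3).to_string(index=False))

best_label = "{algorithm}/{clinical_strategy}/{microbiome_rep}".format(
    **grid.summary.iloc[0])
print(f"\nbest configuration: {best_label}")
report = stability_report(grid.results[best_label])
print("top features by mean importance rank across folds:")
print(report.importance.head(8).round(2).to_string(index=False))

# AUROC ~0.5 would mean no outcome-linked structure; values meaningfully
# above 0.5 here reflect the planted Mycoplasma log-fold-change and the
# simulated clinical contrasts, recovered without leakage.
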