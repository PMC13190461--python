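"""Permutation inference, stability summaries, and sensitivity analyses.

The permutation test asks whether the pipeline's observed mean outer-fold
subject-level AUROC exceeds what label shuffling alone produces. Labels are
permuted strictly at subject level — all longitudinal samples of a subject
inherit its permuted label, preserving the repeated-measures correlation
structure — and each permutation reruns the complete nested CV pipeline
with a fresh fold plan stratified on the permuted labels (the observed
statistic's fold structure is label-dependent, so the null must rebuild
it). The p-value is the conservative estimator (b+1)/(m+1) where b counts
null statistics >= observed; it can never be zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._rng import child_rng
from .cohort import CohortTable
from .config import AnalysisConfig
from .crossval import (ConfigResult, GridResult,
                       make_stratified_subject_folds, run_config, run_grid)
from .da import da_stability
from .errors import CohortCVError, ParameterError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Subject-level label permutation
# ---------------------------------------------------------------------------

def permute_labels_subject_level(outcomes: pd.Series, rng) -> pd.Series:
    """Permute outcome labels across subjects (class totals preserved).

    ``rng`` may be a numpy Generator or an int seed. Every sample of a
    subject inherits the subject's permuted label downstream by
    construction, because labels live on subjects.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(int(rng))
    values = outcomes.to_numpy(copy=True)
    rng.shuffle(values)
    return pd.Series(values, index=outcomes.index, name="outcome")


@dataclass
class PermutationResult:
    observed: float
    null_draws: np.ndarray
    b: int
    m: int
    p_perm: float
    observed_result: ConfigResult | None = None


def permutation_test(cohort: CohortTable, config: AnalysisConfig,
                     m: int = 500, seed: int | None = None,
                     max_retries: int = 5, da_tester=None) -> PermutationResult:
    """Subject-level permutation test of the mean outer-fold AUROC.

    Each of the m replicates reruns the full nested CV on subject-permuted
    labels with a fresh stratified fold plan. Failed replicates (all folds
    degenerate) are redrawn up to ``max_retries`` times, never silently
    dropped.
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    seed = config.seed if seed is None else seed
    observed_result = run_config(cohort, config.replace(seed=seed),
                                 da_tester=da_tester)
    observed = observed_result.mean_auroc()
    if not np.isfinite(observed):
        raise CohortCVError("observed run produced no usable folds")

    null_draws = np.empty(m)
    outcomes = cohort.outcomes
    for i in range(m):
        stat = None
        for attempt in range(max_retries + 1):
            rng = child_rng(seed, "perm", i, attempt)
            permuted = permute_labels_subject_level(outcomes, rng)
            plan = make_stratified_subject_folds(
                permuted, config.k_outer, int(rng.integers(2**31)),
                config.inner_train_fraction)
            res = run_config(cohort, config.replace(seed=seed),
                             fold_plan=plan,
                             outcome_map=permuted.to_dict(),
                             da_tester=da_tester)
            stat = res.mean_auroc()
            if np.isfinite(stat):
                break
            log.warning("permutation %d attempt %d failed; redrawing", i,
                        attempt)
        if stat is None or not np.isfinite(stat):
            raise CohortCVError(f"permutation {i} failed after retries")
        null_draws[i] = stat

    b = int((null_draws >= observed).sum())
    return PermutationResult(observed=float(observed), null_draws=null_draws,
                             b=b, m=m, p_perm=(b + 1) / (m + 1),
                             observed_result=observed_result)


# ---------------------------------------------------------------------------
# Stability report
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    clinical_counts: pd.Series          # variable -> folds selecting it
    importance: pd.DataFrame            # feature, mean_rank, folds_present
    importance_kind: str
    da: pd.DataFrame                    # taxon, detection_count, direction_consistent


def stability_report(result: ConfigResult) -> StabilityReport:
    """Selection/importance stability across the outer folds of one run.

    Clinical counts tally per-variable selection frequency. Importances are
    rank-normalized within each fold (rank 1 = most important) and averaged;
    features absent from a fold's model get that fold's worst rank + 1. For
    elastic-net runs coefficient magnitudes stand in for impurity decrease
    (noted in ``importance_kind``).
    """
    ok = [fr for fr in result.fold_results if fr.status == "ok"]
    k = len(result.fold_results)
    clin = pd.Series(
        [v for fr in ok for v in fr.selected_clinical], dtype=object
    ).value_counts().astype(int)
    clin.name = "selection_count"

    all_features = sorted({f for fr in ok for f in fr.importances})
    ranks, present = [], []
    for fr in ok:
        order = pd.Series(fr.importances).rank(ascending=False,
                                               method="average")
        worst = len(fr.importances) + 1
        ranks.append([float(order.get(f, worst)) for f in all_features])
        present.append([f in fr.importances for f in all_features])
    imp = pd.DataFrame({
        "feature": all_features,
        "mean_rank": np.mean(ranks, axis=0) if ranks else [],
        "folds_present": np.sum(present, axis=0) if present else [],
    }).sort_values("mean_rank", kind="stable").reset_index(drop=True)

    kinds = {fr.importance_kind for fr in ok}
    kind = kinds.pop() if len(kinds) == 1 else "mixed"
    if kind == "coefficient_magnitude":
        log.info("importance from coefficient magnitudes (elastic net)")

    da = da_stability(
        [fr.selected_taxa for fr in ok],
        [{t: 1.0 for t in fr.selected_taxa} for fr in ok])
    if clin.size:
        assert int(clin.max()) <= k
    return StabilityReport(clinical_counts=clin, importance=imp,
                           importance_kind=kind, da=da)


# ---------------------------------------------------------------------------
# Sensitivity analyses
# ---------------------------------------------------------------------------

SENSITIVITY_VARIANTS = ("pseudocount", "lambda", "early", "outlier", "weights")


def restrict_early_samples(cohort: CohortTable,
                           max_ga: float = 28.0) -> CohortTable:
    """Keep only samples collected before ``max_ga`` weeks of gestation."""
    keep = cohort.samples.index[
        cohort.samples["gestational_age_weeks"] < max_ga]
    return cohort.select_samples(keep)


def drop_earliest_delivery(cohort: CohortTable) -> CohortTable:
    """Exclude the subject with the minimum gestational age at delivery
    (the potential extreme-outlier case)."""
    drop = cohort.subjects["ga_delivery_weeks"].idxmin()
    log.info("sensitivity: excluding earliest-delivery subject %s", drop)
    return cohort.select_subjects([s for s in cohort.subjects.index
                                   if s != drop])


def _variant_runs(variant: str, cohort: CohortTable):
    """Yield (level_label, cohort, config-field overrides) per level."""
    if variant == "pseudocount":
        for pc in (0.5, 0.65, 1.0):
            yield f"pseudocount={pc}", cohort, {"pseudocount": pc}
    elif variant == "lambda":
        for lam in (0.001, 0.01, 0.1):
            yield f"lambda={lam}", cohort, {"lambda_": lam}
    elif variant == "early":
        yield "ga<28", restrict_early_samples(cohort), {}
    elif variant == "outlier":
        yield "drop_earliest_delivery", drop_earliest_delivery(cohort), {}
    elif variant == "weights":
        yield "inverse_frequency", cohort, {"weighting": "inverse_frequency"}
    else:
        raise ParameterError(f"unknown sensitivity variant {variant!r}")


@dataclass
class SensitivityResult:
    table: pd.DataFrame                 # variant, level, config axes, metric, mean, sd
    rank_concordance: pd.DataFrame      # variant, level, spearman_rho vs base
    base: GridResult
    infeasible: list[str] = field(default_factory=list)


def sensitivity_suite(cohort: CohortTable, base_config: AnalysisConfig,
                      variants=SENSITIVITY_VARIANTS,
                      configs: list[AnalysisConfig] | None = None,
                      da_tester=None) -> SensitivityResult:
    """Re-run the grid (or a configured subset) under each variant and
    report a long-format comparison plus per-variant rank concordance of
    the configuration ordering against the base run.

    A variant that empties an outcome class is marked infeasible and the
    others proceed.
    """
    base = run_grid(cohort, base_config, configs=configs,
                    da_tester=da_tester)
    long_rows, concordance, infeasible = [], [], []

    def melt(grid: GridResult, variant: str, level: str) -> None:
        for row in grid.summary.itertuples():
            for metric, (mk, sk) in (("auroc", ("auroc_mean", "auroc_sd")),
                                     ("prauc", ("prauc_mean", "prauc_sd")),
                                     ("sensitivity", ("sens_mean", "sens_sd")),
                                     ("specificity", ("spec_mean", "spec_sd")),
                                     ("balanced_accuracy",
                                      ("bal_acc_mean", "bal_acc_sd"))):
                long_rows.append({
                    "variant": variant, "level": level,
                    "algorithm": row.algorithm,
                    "clinical_strategy": row.clinical_strategy,
                    "microbiome_rep": row.microbiome_rep,
                    "metric": metric,
                    "mean": getattr(row, mk), "sd": getattr(row, sk)})

    melt(base, "base", "base")
    base_order = base.summary.set_index(
        ["algorithm", "clinical_strategy", "microbiome_rep"])["auroc_mean"]

    for variant in variants:
        for level, var_cohort, overrides in _variant_runs(variant, cohort):
            if var_cohort.outcomes.nunique() < 2:
                infeasible.append(level)
                log.warning("variant %s empties an outcome class; skipped",
                            level)
                continue
            var_configs = (None if configs is None
                           else [c.replace(**overrides) for c in configs])
            grid = run_grid(var_cohort, base_config.replace(**overrides),
                            configs=var_configs, da_tester=da_tester)
            melt(grid, variant, level)
            var_order = grid.summary.set_index(
                ["algorithm", "clinical_strategy",
                 "microbiome_rep"])["auroc_mean"]
            joined = pd.concat([base_order, var_order], axis=1,
                               join="inner")
            rho = (spearmanr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic
                   if len(joined) > 2 else np.nan)
            concordance.append({"variant": variant, "level": level,
                                "spearman_rho": rho})

    table = pd.DataFrame(long_rows, columns=["variant", "level", "algorithm",
                                             "clinical_strategy",
                                             "microbiome_rep", "metric",
                                             "mean", "sd"])
    return SensitivityResult(
        table=table,
        rank_concordance=pd.DataFrame(concordance,
                                      columns=["variant", "level",
                                               "spearman_rho"]),
        base=base, infeasible=infeasible)
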