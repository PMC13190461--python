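"""Leakage-aware subject-level nested cross-validation.

Outer loop: k stratified folds at subject level — every longitudinal sample
of a subject travels with it, because repeated measures share host biology
and sample-level splitting lets a model memorize subjects instead of
learning outcome structure. Inner loop: a stratified 70/30 subject split of
each outer training set picks the classification threshold maximizing
Youden's J = sensitivity + specificity - 1 on inner-validation subject-level
probabilities; the threshold is then frozen, the model refit on the full
outer training set, and outer-test samples predicted, averaged per subject,
and scored at the frozen threshold. All preprocessing (CLR, differential-
abundance taxon selection, clinical screening) is fitted on the outer
training partition only.

Hyperparameters are fixed a priori and never tuned: a 500-tree probability
forest (4 candidate features per split, minimum node size 10) or an
elastic-net logistic regression at alpha = 0.5, lambda = 0.01 on predictors
standardized by training-fold statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score

from ._rng import child_rng, child_seed
from .clinical import FeatureStrategySpec, select_clinical, subject_level_view
from .cohort import CohortTable
from .compositional import apply_clr, fit_clr, shannon_matrix
from .config import AnalysisConfig, grid_configs
from .da import DEFAULT_DA_COVARIATES, da_test
from .errors import (FitError, MetricsUndefinedError, ParameterError,
                     StratificationError)

log = logging.getLogger(__name__)

METRIC_NAMES = ("auroc", "prauc", "sensitivity", "specificity",
                "balanced_accuracy")


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Subject-level outer folds plus per-fold inner 70/30 splits."""

    k: int
    assignment: dict[str, int]            # subject_id -> fold index 0..k-1
    inner_splits: list[dict[str, list[str]]]
    seed: int

    def outer_train(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f != fold]

    def outer_test(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


def make_stratified_subject_folds(outcomes: pd.Series, k: int, seed: int,
                                  inner_train_fraction: float = 0.70) -> FoldPlan:
    """Deal subjects into k stratified folds.

    Each outcome class is shuffled with the seed and dealt round-robin from
    fold 0, so per-fold class counts differ by at most one and both classes'
    shortfalls stack on the highest-index folds (43 subjects with 14
    positives and k=5 gives fold sizes 9,9,9,9,7 with positive counts
    3,3,3,3,2). When the cohort is so small that aligned dealing would
    leave a fold empty, class deals are staggered so every fold receives a
    subject. A class smaller than k is spread one-per-fold (folds lacking
    that class are handled as degenerate downstream).
    """
    if k < 2:
        raise StratificationError("k must be >= 2")
    outcomes = outcomes.astype(int)
    if len(outcomes) < k:
        raise StratificationError(f"{len(outcomes)} subjects cannot fill {k} folds")
    for cls in (0, 1):
        if (outcomes == cls).sum() == 0:
            raise StratificationError(f"outcome class {cls} has no subjects")

    shuffled = {}
    for cls in (1, 0):
        members = sorted(outcomes.index[outcomes == cls])
        rng = child_rng(seed, "outer", cls)
        rng.shuffle(members)
        shuffled[cls] = members

    def deal(staggered: bool) -> dict[str, int]:
        out, offset = {}, 0
        for cls in (1, 0):
            for j, subject in enumerate(shuffled[cls]):
                out[subject] = (j + offset) % k
            if staggered:
                offset += len(shuffled[cls])
        return out

    assignment = deal(staggered=False)
    if len(set(assignment.values())) < k:
        assignment = deal(staggered=True)

    inner_splits = []
    for f in range(k):
        train = [s for s, fi in assignment.items() if fi != f]
        inner_train, inner_valid = [], []
        for cls in (1, 0):
            members = sorted(s for s in train if outcomes[s] == cls)
            rng = child_rng(seed, "inner", f, cls)
            rng.shuffle(members)
            n = len(members)
            if n < 2:
                inner_train.extend(members)  # too small to hold out
                continue
            n_train = int(np.clip(round(inner_train_fraction * n), 1, n - 1))
            inner_train.extend(members[:n_train])
            inner_valid.extend(members[n_train:])
        inner_splits.append({"inner_train": sorted(inner_train),
                             "inner_valid": sorted(inner_valid)})
    return FoldPlan(k=k, assignment=assignment, inner_splits=inner_splits,
                    seed=seed)


def make_sample_level_folds(sample_outcomes: pd.Series, k: int,
                            seed: int) -> dict[str, int]:
    """Stratified k-fold split of SAMPLES, ignoring subject identity.

    This is a deliberately broken baseline kept only so tests and
    demonstrations can quantify the optimism that repeated measures induce;
    it must never be used for reported results.
    """
    assignment: dict[str, int] = {}
    for cls in (1, 0):
        members = sorted(sample_outcomes.index[sample_outcomes == cls])
        rng = child_rng(seed, "sample_level", cls)
        rng.shuffle(members)
        for j, sample in enumerate(members):
            assignment[sample] = j % k
    return assignment


# ---------------------------------------------------------------------------
# Threshold optimization and metrics
# ---------------------------------------------------------------------------

@dataclass
class ThresholdSearchResult:
    threshold: float
    J: float
    sensitivity_at: float
    specificity_at: float
    degenerate: bool = False


def _sens_spec(probs, labels, threshold) -> tuple[float, float]:
    pred = probs >= threshold  # ties classified positive
    pos, neg = labels == 1, labels == 0
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float((~pred[neg]).mean()) if neg.any() else np.nan
    return sens, spec


def optimize_threshold_youden(subject_probs, subject_labels) -> ThresholdSearchResult:
    """Threshold maximizing Youden's J over candidate cuts.

    Candidates are the midpoints between consecutive distinct sorted
    probabilities plus 0 and 1. Ties favour the smallest maximizing
    threshold (i.e. sensitivity). A single-class validation set falls back
    to 0.5 with a warning (degenerate fold).
    """
    probs = np.asarray(subject_probs, dtype=float)
    labels = np.asarray(subject_labels, dtype=int)
    if np.unique(labels).size < 2:
        log.warning("single-class inner validation set; threshold falls back to 0.5")
        return ThresholdSearchResult(0.5, 0.0, 0.5, 0.5, degenerate=True)
    distinct = np.unique(probs)
    candidates = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2.0, [1.0]])
    best = None
    for t in candidates:
        sens, spec = _sens_spec(probs, labels, t)
        j = sens + spec - 1.0
        if best is None or j > best.J + 1e-12:
            best = ThresholdSearchResult(float(t), float(j), sens, spec)
    return best


def compute_auroc(probs, labels) -> float:
    """Rank (Mann-Whitney) AUROC with midranks for ties."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise MetricsUndefinedError("AUROC needs both classes")
    ranks = rankdata(probs)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_metrics(subject_probs, labels, threshold: float) -> dict[str, float]:
    """Subject-level discrimination metrics at a frozen threshold.

    AUROC by midrank concordance; PRAUC as average precision (step-wise
    integral of precision over recall, positive class = PTB); sensitivity
    and specificity with prediction 1 iff prob >= threshold; balanced
    accuracy as their mean.
    """
    probs = np.asarray(subject_probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise MetricsUndefinedError("metrics need both classes present")
    auroc = compute_auroc(probs, labels)
    prauc = float(average_precision_score(labels, probs))
    sens, spec = _sens_spec(probs, labels, threshold)
    return {"auroc": auroc, "prauc": prauc, "sensitivity": sens,
            "specificity": spec, "balanced_accuracy": (sens + spec) / 2.0}


def aggregate_subject_probs(sample_probs: pd.Series,
                            subject_of: pd.Series) -> pd.Series:
    """Unweighted arithmetic mean of sample-level probabilities per subject."""
    subj = subject_of.reindex(sample_probs.index)
    if subj.isna().any():
        raise ParameterError("every sample must map to a subject")
    return sample_probs.groupby(subj).mean()


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_predict(config: AnalysisConfig, X_train, y_train, X_test,
                sample_weight=None, seed: int = 0) -> np.ndarray:
    """Fit the configured model and return class-1 probabilities for X_test.

    random_forest: probability forest with the fixed hyperparameters
    (min_node maps to the minimum node size eligible for splitting).
    elastic_net: penalized logistic regression at fixed (alpha, lambda) on
    predictors standardized by training mean/SD; the lambda of the
    average-loss formulation maps to C = 1/(n_train * lambda) in the
    summed-loss formulation.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if not (np.isfinite(X_train).all() and np.isfinite(X_test).all()):
        raise ParameterError("non-finite feature values")
    if np.unique(y_train).size < 2:
        raise FitError("training set contains a single class")

    if config.algorithm == "random_forest":
        model = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=min(config.mtry, X_train.shape[1]),
            min_samples_split=config.min_node,
            random_state=seed, n_jobs=1)
        model.fit(X_train, y_train, sample_weight=sample_weight)
        probs = model.predict_proba(X_test)[:, list(model.classes_).index(1)]
        fit_predict.last_model = model
        return probs

    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xtr = (X_train - mu) / sd
    Xte = (X_test - mu) / sd
    c = 1.0 / (len(y_train) * config.lambda_)
    model = LogisticRegression(solver="saga", l1_ratio=config.alpha, C=c,
                               max_iter=5000, tol=1e-4, random_state=seed,
                               warm_start=True)
    # start from the null model (intercept at the weighted base-rate logit),
    # as coordinate-descent elastic-net implementations do; at extreme
    # lambda this is already the optimum
    base = np.average(y_train, weights=sample_weight)
    base = float(np.clip(base, 1e-6, 1 - 1e-6))
    model.coef_ = np.zeros((1, Xtr.shape[1]))
    model.intercept_ = np.array([np.log(base / (1 - base))])
    model.fit(Xtr, y_train, sample_weight=sample_weight)
    probs = model.predict_proba(Xte)[:, list(model.classes_).index(1)]
    fit_predict.last_model = model
    return probs


# ---------------------------------------------------------------------------
# Per-config pipeline
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    status: str                         # "ok", "degenerate" or "failed"
    frozen_threshold: float | None = None
    selected_clinical: list[str] = field(default_factory=list)
    selected_taxa: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    subject_probs: dict[str, float] = field(default_factory=dict)
    subject_labels: dict[str, int] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    importances: dict[str, float] = field(default_factory=dict)
    importance_kind: str = ""
    weight_audit: dict[str, float] = field(default_factory=dict)
    message: str = ""


@dataclass
class ConfigResult:
    config: AnalysisConfig
    fold_plan: FoldPlan
    fold_results: list[FoldResult]
    summary: dict[str, tuple[float, float]]
    n_folds_ok: int

    def mean_auroc(self) -> float:
        return self.summary["auroc"][0]


class _PipelineContext:
    """Arrays precomputed once per run_config; everything here is either
    global (filters already applied) or per-sample leakage-free."""

    def __init__(self, cohort: CohortTable, config: AnalysisConfig,
                 outcomes: pd.Series):
        self.cohort = cohort
        self.config = config
        self.outcomes = outcomes.astype(int)
        self.taxa = cohort.taxa
        self.counts = cohort.counts.to_numpy(dtype=np.int64)
        self.sample_ids = np.asarray(cohort.counts.index)
        self.sample_subject = cohort.subject_of.to_numpy()
        self.sample_outcome = (cohort.subject_of.map(self.outcomes)
                               .to_numpy(dtype=int))
        self.shannon = shannon_matrix(self.counts)
        self.sample_ga = (cohort.samples["gestational_age_weeks"]
                          .to_numpy(dtype=float))
        view = subject_level_view(cohort)
        view["outcome"] = self.outcomes.reindex(view.index)
        self.subject_view = view
        self.cov_types = dict(config.covariate_types)
        # per-subject sample multiplicity for inverse-frequency weighting
        self.samples_per_subject = pd.Series(self.sample_subject).value_counts()

    def sample_mask(self, subjects) -> np.ndarray:
        keep = set(subjects)
        return np.fromiter((s in keep for s in self.sample_subject),
                           dtype=bool, count=len(self.sample_subject))

    def da_covariates(self, mask: np.ndarray):
        cols = [c for c in DEFAULT_DA_COVARIATES
                if c in self.cohort.subjects.columns]
        if not cols:
            return None
        cov = self.cohort.subjects.loc[self.sample_subject[mask], cols]
        return cov.to_numpy(dtype=float)

    def clinical_matrix(self, names, mask, train_subjects) -> np.ndarray:
        """Per-sample numeric matrix for the selected clinical variables.

        Categorical variables are one-hot encoded on the category set seen
        in the training subjects (unseen test categories encode to zeros).
        """
        cols = []
        self._clinical_names = []
        subj = self.sample_subject[mask]
        for name in names:
            if name == "gestational_age_weeks":
                cols.append(self.sample_ga[mask])
                self._clinical_names.append(name)
                continue
            series = self.cohort.subjects[name]
            vtype = self.cov_types.get(
                name, "continuous" if pd.api.types.is_float_dtype(series)
                else "categorical")
            values = series.loc[subj]
            if vtype == "continuous" or pd.api.types.is_numeric_dtype(series):
                cols.append(values.to_numpy(dtype=float))
                self._clinical_names.append(name)
            else:
                cats = sorted(series.loc[list(train_subjects)]
                              .dropna().unique().astype(str))
                for cat in cats[1:] if len(cats) > 1 else cats:
                    cols.append((values.astype(str) == cat)
                                .to_numpy(dtype=float))
                    self._clinical_names.append(f"{name}[{cat}]")
        if not cols:
            return np.empty((int(mask.sum()), 0))
        return np.column_stack(cols)


def _fold_features(ctx: _PipelineContext, train_subjects, train_mask,
                   eval_mask, da_tester):
    """Fit all preprocessing on the training partition and assemble feature
    matrices for the training and evaluation samples."""
    config = ctx.config
    state = fit_clr(ctx.counts[train_mask], config.pseudocount,
                    config.clr_mode)
    clr_train = apply_clr(state, ctx.counts[train_mask])
    clr_eval = apply_clr(state, ctx.counts[eval_mask])

    if config.microbiome_rep == "da_selected":
        tester = da_tester or da_test
        res = tester(clr_train, ctx.sample_outcome[train_mask],
                     covariates=ctx.da_covariates(train_mask), taxa=ctx.taxa)
        selected_taxa = res.loc[res["p"] < config.da_p_threshold,
                                "taxon"].tolist()
    else:
        selected_taxa = list(ctx.taxa)
    taxa_idx = [ctx.taxa.index(t) for t in selected_taxa]

    strategy = FeatureStrategySpec(config.clinical_strategy)
    selected_clinical = select_clinical(
        strategy, ctx.subject_view.loc[list(train_subjects)],
        ctx.cov_types, config.missingness_max)

    def assemble(mask, clr_mat):
        clin = ctx.clinical_matrix(selected_clinical, mask, train_subjects)
        names = (list(ctx._clinical_names) + list(selected_taxa) + ["shannon"])
        X = np.column_stack([clin, clr_mat[:, taxa_idx],
                             ctx.shannon[mask][:, None]])
        return X, names

    X_train, feature_names = assemble(train_mask, clr_train)
    X_eval, _ = assemble(eval_mask, clr_eval)
    return X_train, X_eval, selected_taxa, selected_clinical, feature_names


def _finite_rows(X: np.ndarray) -> np.ndarray:
    return np.isfinite(X).all(axis=1)


def _train_weights(ctx: _PipelineContext, subj: np.ndarray):
    """Inverse-frequency sample weights: 1/n per sample so every subject's
    training samples sum to exactly 1.0."""
    if ctx.config.weighting != "inverse_frequency":
        return None
    counts = pd.Series(subj).value_counts()
    return np.asarray([1.0 / counts[s] for s in subj], dtype=float)


def _run_fold(ctx: _PipelineContext, plan: FoldPlan, fold: int,
              da_tester) -> FoldResult:
    config = ctx.config
    train_subjects = plan.outer_train(fold)
    test_subjects = plan.outer_test(fold)
    train_mask = ctx.sample_mask(train_subjects)
    test_mask = ctx.sample_mask(test_subjects)
    try:
        X_train, X_test, taxa_sel, clin_sel, names = _fold_features(
            ctx, train_subjects, train_mask, test_mask, da_tester)

        ok_train = _finite_rows(X_train)
        if not ok_train.all():
            log.info("fold %d: dropping %d training sample(s) with missing "
                     "features", fold, int((~ok_train).sum()))
        train_subj = ctx.sample_subject[train_mask][ok_train]
        Xtr_all = X_train[ok_train]
        ytr_all = ctx.sample_outcome[train_mask][ok_train]

        # inner loop: fit on inner-train, freeze Youden threshold on
        # inner-validation subject-level probabilities
        split = plan.inner_splits[fold]
        in_train = set(split["inner_train"])
        in_valid = set(split["inner_valid"])
        m_it = np.fromiter((s in in_train for s in train_subj), bool,
                           len(train_subj))
        m_iv = np.fromiter((s in in_valid for s in train_subj), bool,
                           len(train_subj))
        if m_iv.sum() == 0 or np.unique(ytr_all[m_it]).size < 2:
            threshold = ThresholdSearchResult(0.5, 0.0, 0.5, 0.5, True)
        else:
            inner_probs = fit_predict(
                config, Xtr_all[m_it], ytr_all[m_it], Xtr_all[m_iv],
                sample_weight=_train_weights(ctx, train_subj[m_it]),
                seed=child_seed(config.seed, "inner_fit", fold, config.label))
            agg = aggregate_subject_probs(
                pd.Series(inner_probs, index=np.arange(m_iv.sum())),
                pd.Series(train_subj[m_iv], index=np.arange(m_iv.sum())))
            labels = ctx.outcomes.loc[agg.index]
            threshold = optimize_threshold_youden(agg.to_numpy(),
                                                  labels.to_numpy())

        # refit on the full outer training set; the inner model is discarded
        ok_test = _finite_rows(X_test)
        if not ok_test.all():
            log.info("fold %d: dropping %d test sample(s) with missing "
                     "features", fold, int((~ok_test).sum()))
        weights = _train_weights(ctx, train_subj)
        probs = fit_predict(
            config, Xtr_all, ytr_all, X_test[ok_test], sample_weight=weights,
            seed=child_seed(config.seed, "outer_fit", fold, config.label))
        model = fit_predict.last_model
        if hasattr(model, "feature_importances_"):
            importances = dict(zip(names, map(float, model.feature_importances_)))
            imp_kind = "impurity_decrease"
        else:
            importances = dict(zip(names, map(float, np.abs(model.coef_[0]))))
            imp_kind = "coefficient_magnitude"

        test_ids = ctx.sample_ids[test_mask][ok_test]
        subj_probs = aggregate_subject_probs(
            pd.Series(probs, index=test_ids),
            pd.Series(ctx.sample_subject[test_mask][ok_test],
                      index=test_ids))
        subj_labels = ctx.outcomes.loc[subj_probs.index]

        weight_audit = {}
        if weights is not None:
            weight_audit = {s: float(w) for s, w in
                            pd.Series(weights).groupby(train_subj).sum().items()}

        try:
            metrics = compute_metrics(subj_probs.to_numpy(),
                                      subj_labels.to_numpy(),
                                      threshold.threshold)
            status = "ok"
            message = ""
        except MetricsUndefinedError as exc:
            metrics, status, message = {}, "degenerate", str(exc)

        return FoldResult(
            fold=fold, status=status, frozen_threshold=threshold.threshold,
            selected_clinical=clin_sel, selected_taxa=taxa_sel,
            feature_names=names,
            subject_probs={s: float(p) for s, p in subj_probs.items()},
            subject_labels={s: int(v) for s, v in subj_labels.items()},
            metrics=metrics, importances=importances,
            importance_kind=imp_kind, weight_audit=weight_audit,
            message=message)
    except (FitError, ParameterError) as exc:
        log.warning("fold %d failed: %s", fold, exc)
        return FoldResult(fold=fold, status="failed", message=str(exc))


def run_config(cohort: CohortTable, config: AnalysisConfig,
               fold_plan: FoldPlan | None = None,
               outcome_map: dict[str, int] | None = None,
               da_tester=None) -> ConfigResult:
    """Run the full nested-CV pipeline for one configuration.

    ``outcome_map`` overrides subject outcomes (used by the permutation
    test); the cohort itself is never modified. Fold failures are recorded
    per fold, and the summary (mean +- SD per metric) is computed over the
    successful folds.
    """
    outcomes = (pd.Series(outcome_map).reindex(cohort.subjects.index)
                if outcome_map is not None else cohort.outcomes)
    if fold_plan is None:
        fold_plan = make_stratified_subject_folds(
            outcomes, config.k_outer, config.seed,
            config.inner_train_fraction)
    ctx = _PipelineContext(cohort, config, outcomes)
    fold_results = [_run_fold(ctx, fold_plan, f, da_tester)
                    for f in range(fold_plan.k)]
    ok = [fr for fr in fold_results if fr.status == "ok"]
    summary = {}
    for metric in METRIC_NAMES:
        vals = np.asarray([fr.metrics[metric] for fr in ok], dtype=float)
        if vals.size:
            summary[metric] = (float(vals.mean()),
                               float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        else:
            summary[metric] = (float("nan"), float("nan"))
    return ConfigResult(config=config, fold_plan=fold_plan,
                        fold_results=fold_results, summary=summary,
                        n_folds_ok=len(ok))


# ---------------------------------------------------------------------------
# The 12-configuration grid
# ---------------------------------------------------------------------------

GRID_COLUMNS = ["algorithm", "clinical_strategy", "microbiome_rep",
                "auroc_mean", "auroc_sd", "prauc_mean", "prauc_sd",
                "sens_mean", "sens_sd", "spec_mean", "spec_sd",
                "bal_acc_mean", "bal_acc_sd", "n_folds_ok"]

_SUMMARY_KEYS = {"auroc": ("auroc_mean", "auroc_sd"),
                 "prauc": ("prauc_mean", "prauc_sd"),
                 "sensitivity": ("sens_mean", "sens_sd"),
                 "specificity": ("spec_mean", "spec_sd"),
                 "balanced_accuracy": ("bal_acc_mean", "bal_acc_sd")}


@dataclass
class GridResult:
    summary: pd.DataFrame
    results: dict[str, ConfigResult]
    fold_plan: FoldPlan
    base_config: AnalysisConfig


def summarize_configs(results: list[ConfigResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {"algorithm": res.config.algorithm,
               "clinical_strategy": res.config.clinical_strategy,
               "microbiome_rep": res.config.microbiome_rep,
               "n_folds_ok": res.n_folds_ok}
        for metric, (mk, sk) in _SUMMARY_KEYS.items():
            row[mk], row[sk] = res.summary[metric]
        rows.append(row)
    df = pd.DataFrame(rows, columns=GRID_COLUMNS)
    return (df.sort_values("auroc_mean", ascending=False, kind="stable")
            .reset_index(drop=True))


def run_grid(cohort: CohortTable, base_config: AnalysisConfig,
             fold_plan: FoldPlan | None = None,
             configs: list[AnalysisConfig] | None = None,
             da_tester=None) -> GridResult:
    """Evaluate the model grid (12 configurations by default) under one
    shared subject-level fold plan and summarize Table-style, sorted by
    mean AUROC descending."""
    if fold_plan is None:
        fold_plan = make_stratified_subject_folds(
            cohort.outcomes, base_config.k_outer, base_config.seed,
            base_config.inner_train_fraction)
    configs = configs if configs is not None else grid_configs(base_config)
    results = {c.label: run_config(cohort, c, fold_plan=fold_plan,
                                   da_tester=da_tester) for c in configs}
    summary = summarize_configs(list(results.values()))
    return GridResult(summary=summary, results=results, fold_plan=fold_plan,
                      base_config=base_config)


# ---------------------------------------------------------------------------
# Leakage diagnostic
# ---------------------------------------------------------------------------

def cv_auroc(cohort: CohortTable, config: AnalysisConfig,
             level: str = "subject", da_tester=None) -> float:
    """Mean k-fold cross-validated AUROC under subject-level or (broken,
    diagnostic-only) sample-level splitting.

    The sample-level mode exists so the repeated-measures optimism can be
    measured: on a cohort with strong subject effects and no outcome signal
    it inflates AUROC above chance, while subject-level splitting does not.
    No threshold is involved (AUROC is threshold-free), so the inner loop
    is skipped.
    """
    outcomes = cohort.outcomes
    ctx = _PipelineContext(cohort, config, outcomes)
    aurocs = []
    if level == "subject":
        plan = make_stratified_subject_folds(outcomes, config.k_outer,
                                             config.seed)
        folds = [(plan.outer_train(f), None, plan.outer_test(f), None)
                 for f in range(config.k_outer)]
    elif level == "sample":
        sample_out = pd.Series(ctx.sample_outcome, index=ctx.sample_ids)
        assign = make_sample_level_folds(sample_out, config.k_outer,
                                         config.seed)
        folds = []
        for f in range(config.k_outer):
            tr = [s for s, fi in assign.items() if fi != f]
            te = [s for s, fi in assign.items() if fi == f]
            tr_subj = sorted(set(cohort.subject_of.loc[tr]))
            folds.append((tr_subj, tr, None, te))
    else:
        raise ParameterError("level must be 'subject' or 'sample'")

    sample_pos = {s: i for i, s in enumerate(ctx.sample_ids)}
    for f, (train_subjects, train_samples, test_subjects, test_samples) in \
            enumerate(folds):
        if train_samples is None:
            train_mask = ctx.sample_mask(train_subjects)
            test_mask = ctx.sample_mask(test_subjects)
        else:
            train_mask = np.zeros(len(ctx.sample_ids), dtype=bool)
            train_mask[[sample_pos[s] for s in train_samples]] = True
            test_mask = np.zeros(len(ctx.sample_ids), dtype=bool)
            test_mask[[sample_pos[s] for s in test_samples]] = True

        X_train, X_test, _, _, _ = _fold_features(
            ctx, train_subjects, train_mask, test_mask, da_tester)
        ok = _finite_rows(X_train)
        probs = fit_predict(
            config, X_train[ok], ctx.sample_outcome[train_mask][ok], X_test,
            seed=child_seed(config.seed, "cv_auroc", level, f))
        if level == "subject":
            agg = aggregate_subject_probs(
                pd.Series(probs, index=ctx.sample_ids[test_mask]),
                pd.Series(ctx.sample_subject[test_mask],
                          index=ctx.sample_ids[test_mask]))
            aurocs.append(compute_auroc(agg.to_numpy(),
                                        outcomes.loc[agg.index].to_numpy()))
        else:
            aurocs.append(compute_auroc(probs,
                                        ctx.sample_outcome[test_mask]))
    return float(np.mean(aurocs))
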