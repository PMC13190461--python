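"""Fold construction, threshold freezing, metrics, and the nested pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import cohortcv as cc
from cohortcv.errors import (FitError, MetricsUndefinedError, ParameterError,
                             StratificationError)


def _outcomes(n_pos, n_neg):
    labels = [1] * n_pos + [0] * n_neg
    return pd.Series(labels, index=[f"p{i}" for i in range(len(labels))])


class TestFoldConstruction:
    def test_study_structure_43_subjects(self):
        plan = cc.make_stratified_subject_folds(_outcomes(14, 29), 5, seed=0)
        sizes = sorted((pd.Series(plan.assignment).value_counts()).tolist())
        assert sizes == [7, 9, 9, 9, 9]
        outcome = _outcomes(14, 29)
        ptb = sorted(pd.Series(plan.assignment)[outcome == 1]
                     .value_counts().reindex(range(5), fill_value=0).tolist())
        assert ptb == [2, 3, 3, 3, 3]

    def test_one_subject_per_fold(self):
        plan = cc.make_stratified_subject_folds(_outcomes(2, 3), 5, seed=1)
        counts = pd.Series(plan.assignment).value_counts()
        assert counts.tolist() == [1] * 5

    def test_exhaustive_small_case(self):
        plan = cc.make_stratified_subject_folds(_outcomes(4, 6), 2, seed=2)
        assign = pd.Series(plan.assignment)
        outcome = _outcomes(4, 6)
        for fold in (0, 1):
            assert (assign == fold).sum() == 5
            assert ((assign == fold) & (outcome == 1)).sum() == 2

    def test_missing_class_rejected(self):
        with pytest.raises(StratificationError):
            cc.make_stratified_subject_folds(_outcomes(0, 10), 5, seed=0)
        with pytest.raises(StratificationError):
            cc.make_stratified_subject_folds(_outcomes(2, 1), 5, seed=0)

    def test_samples_inherit_subject_fold(self, small_cohort):
        plan = cc.make_stratified_subject_folds(small_cohort.outcomes, 5, 0)
        sample_folds = small_cohort.subject_of.map(plan.assignment)
        per_subject = sample_folds.groupby(small_cohort.subject_of).nunique()
        assert (per_subject == 1).all()

    def test_inner_split_partitions_training_subjects(self):
        outcomes = _outcomes(14, 29)
        plan = cc.make_stratified_subject_folds(outcomes, 5, seed=3)
        for f in range(5):
            split = plan.inner_splits[f]
            train = set(plan.outer_train(f))
            inner = set(split["inner_train"]) | set(split["inner_valid"])
            assert inner == train
            assert not set(split["inner_train"]) & set(split["inner_valid"])
            frac = len(split["inner_train"]) / len(train)
            assert 0.55 < frac < 0.85


class TestYouden:
    def test_separable_case(self):
        res = cc.optimize_threshold_youden([0.2, 0.4, 0.6, 0.8], [0, 0, 1, 1])
        assert res.threshold == pytest.approx(0.5)
        assert res.J == pytest.approx(1.0)
        assert res.J == pytest.approx(res.sensitivity_at
                                      + res.specificity_at - 1.0)

    def test_uninformative_scores(self):
        res = cc.optimize_threshold_youden([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert res.J == pytest.approx(0.0)

    def test_single_class_fallback(self):
        res = cc.optimize_threshold_youden([0.2, 0.6], [1, 1])
        assert res.threshold == 0.5 and res.degenerate

    def test_matches_brute_force_grid(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            probs = np.round(rng.random(30), 2)
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            res = cc.optimize_threshold_youden(probs, labels)
            best_j = -np.inf
            for t in np.unique(np.r_[0.0, probs - 1e-9, probs + 1e-9, 1.0]):
                pred = probs >= t
                sens = pred[labels == 1].mean()
                spec = (~pred[labels == 0]).mean()
                best_j = max(best_j, sens + spec - 1)
            assert res.J == pytest.approx(best_j, abs=1e-9)


class TestMetrics:
    def test_perfect_ranking(self):
        m = cc.compute_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5)
        assert m["auroc"] == 1.0 and m["prauc"] == 1.0

    def test_auroc_three_of_four_concordant(self):
        assert cc.compute_auroc([0.1, 0.4, 0.35, 0.8],
                                [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_reversed_scores_complement(self):
        rng = np.random.default_rng(5)
        probs = rng.permutation(np.linspace(0.01, 0.99, 20))  # no ties
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        a = cc.compute_auroc(probs, labels)
        assert cc.compute_auroc(-probs, labels) == pytest.approx(1 - a)

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(6)
        probs = rng.integers(0, 5, 50) / 4.0
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert cc.compute_auroc(probs, labels) == pytest.approx(
            roc_auc_score(labels, probs))

    def test_balanced_accuracy_identity_and_threshold_rule(self):
        probs = [0.3, 0.5, 0.5, 0.9]
        labels = [0, 0, 1, 1]
        m = cc.compute_metrics(probs, labels, 0.5)
        # ties at the threshold classify positive
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.5
        assert m["balanced_accuracy"] == pytest.approx(
            (m["sensitivity"] + m["specificity"]) / 2)

    def test_single_class_undefined(self):
        with pytest.raises(MetricsUndefinedError):
            cc.compute_metrics([0.2, 0.8], [1, 1], 0.5)


class TestAggregation:
    def test_basic_arithmetic(self):
        probs = pd.Series([0.2, 0.4, 0.9], index=["s1", "s2", "s3"])
        subj = pd.Series(["a", "a", "b"], index=["s1", "s2", "s3"])
        agg = cc.aggregate_subject_probs(probs, subj)
        assert agg["a"] == pytest.approx(0.3)
        assert agg["b"] == pytest.approx(0.9)

    def test_random_fixture_matches_manual_groupby(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(40)]
        probs = pd.Series(rng.random(40), index=ids)
        subj = pd.Series(rng.choice(["a", "b", "c", "d"], 40), index=ids)
        agg = cc.aggregate_subject_probs(probs, subj)
        for s in "abcd":
            members = [i for i in ids if subj[i] == s]
            assert agg[s] == pytest.approx(
                sum(probs[m] for m in members) / len(members))

    def test_unmapped_sample_rejected(self):
        probs = pd.Series([0.2], index=["s1"])
        with pytest.raises(ParameterError):
            cc.aggregate_subject_probs(probs, pd.Series(dtype=object))


class TestFitPredict:
    def _sep_data(self, n=60):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, n)
        X = np.column_stack([y * 4.0 + rng.normal(0, 0.2, n),
                             rng.normal(size=n)])
        return X, y

    @pytest.mark.parametrize("algorithm", ["random_forest", "elastic_net"])
    def test_separable_feature_gives_perfect_test_auroc(self, algorithm):
        X, y = self._sep_data()
        config = cc.AnalysisConfig(algorithm=algorithm, n_trees=100)
        probs = cc.fit_predict(config, X[:40], y[:40], X[40:], seed=1)
        assert cc.compute_auroc(probs, y[40:]) == 1.0

    def test_full_shrinkage_limit_returns_base_rate(self):
        X, y = self._sep_data()
        config = cc.AnalysisConfig(algorithm="elastic_net", lambda_=1e6)
        probs = cc.fit_predict(config, X, y, X, seed=1)
        assert np.allclose(probs, y.mean(), atol=1e-3)

    def test_error_conditions(self):
        X, y = self._sep_data()
        config = cc.AnalysisConfig(algorithm="elastic_net")
        with pytest.raises(ParameterError):
            bad = X.copy()
            bad[0, 0] = np.nan
            cc.fit_predict(config, bad, y, X)
        with pytest.raises(FitError):
            cc.fit_predict(config, X, np.zeros_like(y), X)


class TestRunConfig:
    def test_inverse_frequency_weights_sum_to_one(self, small_cohort,
                                                  fast_en_config):
        config = fast_en_config.replace(weighting="inverse_frequency")
        res = cc.run_config(small_cohort, config)
        for fr in res.fold_results:
            assert fr.weight_audit
            for total in fr.weight_audit.values():
                assert total == pytest.approx(1.0)

    def test_frozen_threshold_immune_to_test_fold(self, small_cohort,
                                                  fast_en_config):
        """Mutating outer-test data (labels and counts) must leave the
        frozen threshold and the feature selections unchanged."""
        config = fast_en_config.replace(microbiome_rep="da_selected",
                                        clinical_strategy="data_driven")
        plan = cc.make_stratified_subject_folds(small_cohort.outcomes,
                                                config.k_outer, config.seed)
        base = cc.run_config(small_cohort, config, fold_plan=plan)

        mutated = small_cohort.copy()
        victims = plan.outer_test(0)
        flipped = small_cohort.outcomes.to_dict()
        for s in victims:
            flipped[s] = 1 - flipped[s]
            mutated.subjects.loc[s, "ga_delivery_weeks"] = (
                34.0 if flipped[s] else 39.0)
        mutated.subjects["outcome"] = pd.Series(flipped)
        test_samples = mutated.subject_of.isin(victims)
        mutated.counts.loc[test_samples] = (
            mutated.counts.loc[test_samples].to_numpy()[::-1])
        other = cc.run_config(mutated, config, fold_plan=plan,
                              outcome_map=flipped)
        assert (base.fold_results[0].frozen_threshold
                == other.fold_results[0].frozen_threshold)
        assert (base.fold_results[0].selected_taxa
                == other.fold_results[0].selected_taxa)
        assert (base.fold_results[0].selected_clinical
                == other.fold_results[0].selected_clinical)

    def test_determinism(self, small_cohort, fast_en_config):
        a = cc.run_config(small_cohort, fast_en_config)
        b = cc.run_config(small_cohort, fast_en_config)
        assert a.summary == b.summary
        assert [fr.subject_probs for fr in a.fold_results] == \
            [fr.subject_probs for fr in b.fold_results]

    def test_fold_cardinality_and_test_coverage(self, small_cohort,
                                                fast_en_config):
        res = cc.run_config(small_cohort, fast_en_config)
        assert len(res.fold_results) == fast_en_config.k_outer
        covered = sorted(itertools.chain.from_iterable(
            fr.subject_probs for fr in res.fold_results))
        assert covered == sorted(small_cohort.subjects.index)


class TestRunGrid:
    def test_twelve_rows_sorted_by_auroc(self, small_cohort, fast_en_config):
        grid = cc.run_grid(small_cohort, fast_en_config,
                           configs=cc.grid_configs(
                               fast_en_config,
                               algorithms=("elastic_net",)))
        assert len(grid.summary) == 6
        assert (grid.summary["auroc_mean"].to_numpy()
                == np.sort(grid.summary["auroc_mean"])[::-1]).all()
        full = cc.grid_configs(fast_en_config)
        assert len(full) == 12
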