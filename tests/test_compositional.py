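"""Filters, CLR transform, contaminant scoring, Shannon diversity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio.stats.composition import clr as skbio_clr
from skbio.diversity.alpha import shannon as skbio_shannon

import cohortcv as cc
from cohortcv.errors import EmptyTableError, ParameterError, StateError

from conftest import make_minimal_cohort


class TestClrClosedForms:
    def test_equal_parts_map_to_zero(self):
        assert np.allclose(cc.clr_transform([1, 1, 1, 1], 0.65), 0.0)
        assert np.allclose(cc.clr_transform([7, 7, 7], 2.0), 0.0)

    def test_two_part_closed_form(self):
        # pseudocounted vector (e^2, 1): geometric mean e, CLR = (1, -1)
        pc = 0.65
        row = np.array([math.e ** 2 - pc, 1 - pc])
        assert np.allclose(cc.clr_transform(row, pc), [1.0, -1.0])

    def test_term_by_term_formula(self):
        counts, pc = np.array([10, 30, 60]), 0.65
        x = counts + pc
        g = math.prod(x) ** (1 / 3)
        expected = [math.log(v / g) for v in x]
        got = cc.clr_transform(counts, pc)
        assert np.allclose(got, expected)
        assert abs(got.sum()) < 1e-9

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(12, 7))
        ours = cc.clr_matrix(counts, 0.65)
        theirs = skbio_clr(counts + 0.65)
        assert np.allclose(ours, theirs)

    def test_dimension_error(self):
        with pytest.raises(ParameterError):
            cc.clr_transform([5], 0.65)
        with pytest.raises(ParameterError):
            cc.clr_transform([5, 5], 0.0)


class TestClrProperties:
    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10**6),
                    min_size=2, max_size=60))
    def test_rows_sum_to_zero(self, counts):
        out = cc.clr_transform(np.array(counts), 0.65)
        assert abs(out.sum()) < 1e-9

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10**4),
                    min_size=2, max_size=30),
           st.floats(min_value=0.1, max_value=50.0))
    def test_scale_invariance_of_pseudocounted_composition(self, counts, c):
        pc = 0.65
        base = np.array(counts, dtype=float)
        scaled = (base + pc) * c - pc  # pseudocounted vector scaled by c
        a = cc.clr_transform(base, pc)
        b = cc.clr_transform(scaled, pc)
        assert np.allclose(a, b, atol=1e-8)


class TestClrFitState:
    def test_per_sample_ignores_training_set(self):
        rng = np.random.default_rng(1)
        train = rng.integers(0, 100, (8, 5))
        held = rng.integers(0, 100, (3, 5))
        s1 = cc.fit_clr(train, 0.65, "per_sample")
        s2 = cc.fit_clr(train[::-1], 0.65, "per_sample")
        assert np.allclose(cc.apply_clr(s1, held), cc.apply_clr(s2, held))

    def test_train_anchored_state_pure_function_of_train(self):
        rng = np.random.default_rng(2)
        train = rng.integers(0, 100, (8, 5))
        state = cc.fit_clr(train, 0.65, "train_anchored")
        again = cc.fit_clr(train, 0.65, "train_anchored")
        assert np.allclose(state.reference_log_means,
                           again.reference_log_means)
        # held-out data never enters the fit signature at all
        with pytest.raises(StateError):
            cc.ClrFitState(mode="train_anchored", pseudocount=0.65)

    def test_modes_agree_on_constant_composition(self):
        train = np.tile([10, 20, 40, 80], (6, 1))
        anchored = cc.fit_clr(train, 0.65, "train_anchored")
        per_sample = cc.fit_clr(train, 0.65, "per_sample")
        assert np.allclose(cc.apply_clr(anchored, train),
                           cc.apply_clr(per_sample, train))


class TestFilters:
    def _cohort_with_libraries(self, sizes):
        counts = np.column_stack([np.asarray(sizes) - 10,
                                  np.full(len(sizes), 10)])
        return make_minimal_cohort(counts)

    def test_library_size_boundary(self):
        cohort = self._cohort_with_libraries([2999, 3000, 50000])
        out = cc.filter_library_size(cohort, 3000)
        assert out.n_samples == 2
        assert out.library_sizes.min() == 3000  # "below 3,000" excluded

    def test_library_filter_zero_is_identity_and_idempotent(self, default_cohort):
        out = cc.filter_library_size(default_cohort, 0)
        pd.testing.assert_frame_equal(out.counts, default_cohort.counts)
        once = cc.filter_library_size(default_cohort, 3000)
        twice = cc.filter_library_size(once, 3000)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_prevalence_boundary_five_of_110(self):
        # 5/110 = 0.0455 < 0.05 -> removed; 6/110 = 0.0545 -> kept
        counts = np.zeros((110, 3), dtype=int)
        counts[:, 0] = 100
        counts[:5, 1] = 1
        counts[:6, 2] = 1
        cohort = make_minimal_cohort(counts, taxa=["keep", "rare5", "rare6"])
        out = cc.prevalence_filter(cohort, 0.05)
        assert out.taxa == ["keep", "rare6"]

    def test_prevalence_zero_identity_and_all_zero_column(self):
        counts = np.array([[5, 0, 1], [2, 0, 0], [3, 0, 4], [1, 0, 2]])
        cohort = make_minimal_cohort(counts, taxa=["a", "zero", "b"])
        assert cc.prevalence_filter(cohort, 0.0).taxa == ["a", "zero", "b"]
        assert cc.prevalence_filter(cohort, 0.05).taxa == ["a", "b"]

    def test_prevalence_empty_table_error(self):
        cohort = make_minimal_cohort(np.zeros((4, 2), dtype=int) + 1)
        with pytest.raises(EmptyTableError):
            cc.prevalence_filter(
                make_minimal_cohort(np.zeros((4, 2), dtype=int)), 0.5)
        assert cc.prevalence_filter(cohort, 0.5).n_taxa == 2

    def test_curated_blocklist_removes_ten_entries(self):
        rng = np.random.default_rng(0)
        taxa = [f"Genus_{i}" for i in range(77)] + list(cc.DEFAULT_BLOCKLIST)
        counts = rng.integers(1, 50, size=(6, len(taxa)))
        cohort = make_minimal_cohort(counts, taxa=taxa)
        assert cohort.n_taxa == 87
        out = cc.remove_curated_contaminants(cohort)
        assert out.n_taxa == 77  # 9 reagent genera + chloroplast removed

    def test_curated_blocklist_edge_cases(self, default_cohort):
        identity = cc.remove_curated_contaminants(default_cohort, [])
        assert identity.taxa == default_cohort.taxa
        absent = cc.remove_curated_contaminants(default_cohort,
                                                ["NotARealGenus"])
        assert absent.taxa == default_cohort.taxa

    def test_pipeline_order_and_determinism(self, default_cohort):
        config = cc.AnalysisConfig()
        out1, audit = cc.preprocess_cohort(default_cohort, config)
        out2, _ = cc.preprocess_cohort(default_cohort, config)
        pd.testing.assert_frame_equal(out1.counts, out2.counts)
        assert [a["step"] for a in audit] == [
            "library_size_filter", "curated_decontamination",
            "prevalence_filter"]


class TestFrequencyScores:
    def test_taxon_present_once_gets_p_one(self):
        counts = np.zeros((12, 2), dtype=int)
        counts[:, 0] = 1000
        counts[0, 1] = 10
        cohort = make_minimal_cohort(counts, taxa=["bulk", "singleton"],
                                     dna=np.linspace(1, 20, 12))
        scores = cc.frequency_contaminant_scores(cohort)
        assert scores["singleton"] == 1.0

    def test_requires_concentrations(self, default_cohort):
        stripped = default_cohort.copy()
        stripped.samples = stripped.samples.drop(columns=["dna_concentration"])
        with pytest.raises(ParameterError):
            cc.frequency_contaminant_scores(stripped)

    def test_null_taxon_rarely_flagged(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            n = 200
            conc = np.exp(rng.normal(np.log(10), 0.8, n))
            # frequency independent of concentration
            frac = np.exp(rng.normal(np.log(0.02), 0.4, n))
            lib = 30000
            other = np.round(lib * (1 - frac)).astype(int)
            target = np.round(lib * frac).astype(int)
            counts = np.column_stack([other, target])
            cohort = make_minimal_cohort(counts, taxa=["bulk", "indep"],
                                         dna=conc)
            hits += cc.frequency_contaminant_scores(cohort)["indep"] > 0.10
        assert hits >= 0.9 * n_seeds


class TestShannon:
    @pytest.mark.parametrize("row,expected", [
        ([0, 12, 0], 0.0),
        ([3, 3, 3, 3], math.log(4)),
        ([5, 5], math.log(2)),
    ])
    def test_closed_forms(self, row, expected):
        assert cc.shannon_diversity(row) == pytest.approx(expected)

    def test_all_zero_row_undefined(self):
        with pytest.raises(ParameterError):
            cc.shannon_diversity([0, 0, 0])

    def test_matches_reference_and_bounds(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 200, size=(10, 6)) + 1
        ours = cc.shannon_matrix(counts)
        theirs = [skbio_shannon(row, base=math.e) for row in counts]
        assert np.allclose(ours, theirs)
        assert (ours >= 0).all() and (ours <= math.log(6) + 1e-12).all()
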