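import numpy as np
import pandas as pd
import pytest

import cohortcv as cc


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort (43 subjects, 14 PTB)."""
    return cc.generate_cohort(cc.CohortParams(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for pipeline-level tests that fit many model runs."""
    params = cc.CohortParams(n_subjects=24, n_ptb=8, n_taxa=20, seed=11)
    return cc.generate_cohort(params)


@pytest.fixture()
def fast_en_config():
    """The cheapest full pipeline configuration (no screening, no DA)."""
    return cc.AnalysisConfig(algorithm="elastic_net",
                             clinical_strategy="dream_minimal",
                             microbiome_rep="full_filtered", seed=3)


@pytest.fixture()
def toy_cohort_files(tmp_path):
    """Hand-written 3-sample, 2-taxon cohort files."""
    (tmp_path / "counts.tsv").write_text(
        "sample_id\tLactobacillus\tGardnerella\n"
        "s1\t90\t10\n"
        "s2\t50\t50\n"
        "s3\t5\t95\n")
    (tmp_path / "samples.csv").write_text(
        "sample_id,subject_id,gestational_age_weeks,dna_concentration\n"
        "s1,p1,12.0,8.5\n"
        "s2,p1,24.5,12.0\n"
        "s3,p2,30.0,3.2\n")
    (tmp_path / "subjects.csv").write_text(
        "subject_id,outcome,ga_delivery_weeks,maternal_age,pprom\n"
        "p1,0,39.2,28.0,0\n"
        "p2,1,34.0,24.0,1\n")
    return (tmp_path / "counts.tsv", tmp_path / "samples.csv",
            tmp_path / "subjects.csv")


def make_minimal_cohort(counts: np.ndarray, taxa=None, subjects_per_sample=None,
                        outcomes=None, dna=None, ga=None) -> cc.CohortTable:
    """Assemble a CohortTable directly from arrays (helper for unit tests)."""
    n = counts.shape[0]
    taxa = taxa or [f"T{j}" for j in range(counts.shape[1])]
    sample_ids = [f"s{i}" for i in range(n)]
    subjects_per_sample = subjects_per_sample or [f"p{i}" for i in range(n)]
    counts_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"),
                             columns=taxa)
    samples = pd.DataFrame({
        "subject_id": subjects_per_sample,
        "gestational_age_weeks": ga if ga is not None else np.full(n, 20.0),
    }, index=counts_df.index)
    if dna is not None:
        samples["dna_concentration"] = dna
    subj_ids = list(dict.fromkeys(subjects_per_sample))
    if outcomes is None:
        outcomes = {p: 0 for p in subj_ids}
    subjects = pd.DataFrame({
        "outcome": [outcomes[p] for p in subj_ids],
        "ga_delivery_weeks": [34.0 if outcomes[p] else 39.0 for p in subj_ids],
    }, index=pd.Index(subj_ids, name="subject_id"))
    return cc.CohortTable(counts_df, samples, subjects)
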