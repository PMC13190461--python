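"""Cohort data model and on-disk formats.

A cohort is a genus-level count table (samples x taxa), a sample registry
(sample -> subject, gestational age at collection, optional DNA
concentration), and a subject registry (binary preterm-birth outcome,
gestational age at delivery, clinical covariates). Preterm birth (PTB) is
delivery before 37 completed weeks; the outcome column, when absent, is
derived from the delivery age, and a conflict between the two is a
validation error.

Formats are deliberately plain: a tab-separated counts table with samples as
rows and genera as columns, and two CSVs for the registries. Missing
covariate values are empty cells and are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortValidationError, ParseError

log = logging.getLogger(__name__)

#: Sample-registry columns with reserved meaning; anything else is ignored.
SAMPLE_COLUMNS = ("subject_id", "gestational_age_weeks", "dna_concentration")
#: Subject-registry columns with reserved meaning; remaining columns are
#: treated as clinical covariates.
SUBJECT_RESERVED = ("outcome", "ga_delivery_weeks")

PTB_CUTOFF_WEEKS = 37.0


@dataclass
class CohortTable:
    """Counts matrix plus sample and subject registries.

    Attributes
    ----------
    counts : DataFrame, samples x taxa, non-negative integers, indexed by
        sample id.
    samples : DataFrame indexed by sample id with columns ``subject_id``,
        ``gestational_age_weeks`` and optionally ``dna_concentration``.
    subjects : DataFrame indexed by subject id with columns ``outcome``
        (PTB=1), ``ga_delivery_weeks`` and one column per clinical covariate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    subjects: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    # -- convenience views ------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return len(self.counts)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def subject_of(self) -> pd.Series:
        """sample id -> subject id."""
        return self.samples["subject_id"]

    @property
    def outcomes(self) -> pd.Series:
        """subject id -> binary outcome (PTB=1)."""
        return self.subjects["outcome"]

    def sample_outcomes(self) -> pd.Series:
        """Per-sample outcome inherited from each sample's subject."""
        return self.subject_of.map(self.outcomes).rename("outcome")

    def clinical_columns(self) -> list[str]:
        return [c for c in self.subjects.columns if c not in SUBJECT_RESERVED]

    def copy(self) -> "CohortTable":
        return CohortTable(self.counts.copy(), self.samples.copy(),
                           self.subjects.copy(), dict(self.attrs))

    # -- subsetting -------------------------------------------------------
    def select_samples(self, sample_ids, drop_empty_subjects: bool = True) -> "CohortTable":
        """Restrict to the given samples; optionally drop subjects that end
        up with zero samples (logged)."""
        sample_ids = [s for s in self.counts.index if s in set(sample_ids)]
        counts = self.counts.loc[sample_ids]
        samples = self.samples.loc[sample_ids]
        subjects = self.subjects
        if drop_empty_subjects:
            kept = set(samples["subject_id"])
            dropped = [s for s in subjects.index if s not in kept]
            if dropped:
                log.warning("dropping %d subject(s) left with zero samples: %s",
                            len(dropped), dropped)
            subjects = subjects.loc[[s for s in subjects.index if s in kept]]
        return CohortTable(counts, samples, subjects, dict(self.attrs))

    def select_subjects(self, subject_ids) -> "CohortTable":
        keep = set(subject_ids)
        sample_ids = [s for s in self.counts.index
                      if self.samples.loc[s, "subject_id"] in keep]
        return CohortTable(self.counts.loc[sample_ids],
                           self.samples.loc[sample_ids],
                           self.subjects.loc[[s for s in self.subjects.index
                                              if s in keep]],
                           dict(self.attrs))

    def select_taxa(self, taxa) -> "CohortTable":
        taxa = [t for t in self.counts.columns if t in set(taxa)]
        return CohortTable(self.counts[taxa], self.samples.copy(),
                           self.subjects.copy(), dict(self.attrs))


def validate_cohort(cohort: CohortTable) -> list[str]:
    """Check every cohort invariant; returns a list of violation
    descriptions (empty iff the cohort is valid). Never raises."""
    v: list[str] = []
    counts, samples, subjects = cohort.counts, cohort.samples, cohort.subjects

    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        v.append(f"duplicate sample_id in counts: {dups}")
    if samples.index.has_duplicates:
        dups = samples.index[samples.index.duplicated()].unique().tolist()
        v.append(f"duplicate sample_id in sample registry: {dups}")
    if subjects.index.has_duplicates:
        dups = subjects.index[subjects.index.duplicated()].unique().tolist()
        v.append(f"duplicate subject_id: {dups}")
    if counts.columns.has_duplicates:
        v.append("duplicate taxon names in counts header")
    if list(counts.index) != list(samples.index):
        v.append("counts rows and sample registry do not list the same samples"
                 " in the same order")

    arr = counts.to_numpy()
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        v.append("counts matrix contains non-numeric entries")
    else:
        if arr.size and (arr < 0).any():
            bad = counts.index[(arr < 0).any(axis=1)].tolist()
            v.append(f"negative counts in sample(s): {bad}")
        if arr.size and not np.allclose(arr, np.round(arr)):
            v.append("counts matrix contains non-integer entries")

    if "subject_id" not in samples.columns:
        v.append("sample registry lacks subject_id column")
    else:
        known = set(subjects.index)
        orphans = samples.index[~samples["subject_id"].isin(known)].tolist()
        if orphans:
            v.append(f"sample(s) whose subject is not registered: {orphans}")
        seen = set(samples["subject_id"])
        empty = [s for s in subjects.index if s not in seen]
        if empty:
            v.append(f"subject(s) with no samples: {empty}")

    if "gestational_age_weeks" in samples.columns:
        ga = pd.to_numeric(samples["gestational_age_weeks"], errors="coerce")
        bad = samples.index[~ga.between(4, 45, inclusive="neither")].tolist()
        if bad:
            v.append(f"gestational_age_weeks outside (4, 45) for sample(s): {bad}")
    else:
        v.append("sample registry lacks gestational_age_weeks column")

    if "outcome" not in subjects.columns or "ga_delivery_weeks" not in subjects.columns:
        v.append("subject registry lacks outcome and/or ga_delivery_weeks")
    else:
        out = subjects["outcome"]
        if not out.isin([0, 1]).all():
            v.append("outcome must be binary 0/1")
        else:
            expected = (subjects["ga_delivery_weeks"] < PTB_CUTOFF_WEEKS).astype(int)
            clash = subjects.index[out.astype(int) != expected].tolist()
            if clash:
                v.append("outcome conflicts with ga_delivery_weeks (<37 rule) "
                         f"for subject(s): {clash}")
    return v


def _require_valid(cohort: CohortTable) -> CohortTable:
    violations = validate_cohort(cohort)
    if violations:
        raise CohortValidationError(violations)
    return cohort


def read_cohort(counts_path, sample_meta_path, subject_meta_path) -> CohortTable:
    """Read and validate a cohort from its three on-disk files.

    Raises ``ParseError`` on a malformed numeric cell (named by row and
    column) and ``CohortValidationError`` on invariant violations.
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    cols = {}
    for col in raw.columns:
        try:
            cols[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError):
            converted = pd.to_numeric(raw[col], errors="coerce")
            row = raw.index[converted.isna() & raw[col].notna()][0]
            raise ParseError(
                f"malformed numeric cell in counts at row {row!r}, "
                f"column {col!r}: {raw.loc[row, col]!r}") from None
    counts = pd.DataFrame(cols, index=raw.index)

    samples = pd.read_csv(sample_meta_path, index_col=0)
    samples.index = samples.index.astype(str)
    if "subject_id" in samples.columns:
        samples["subject_id"] = samples["subject_id"].astype(str)

    subjects = pd.read_csv(subject_meta_path, index_col=0)
    subjects.index = subjects.index.astype(str)
    if "outcome" not in subjects.columns and "ga_delivery_weeks" in subjects.columns:
        subjects["outcome"] = (subjects["ga_delivery_weeks"]
                               < PTB_CUTOFF_WEEKS).astype(int)

    cohort = CohortTable(counts, samples, subjects)
    _require_valid(cohort)
    cohort.counts = cohort.counts.astype(np.int64)
    if "outcome" in cohort.subjects.columns:
        cohort.subjects["outcome"] = cohort.subjects["outcome"].astype(int)
    return cohort


def write_cohort(cohort: CohortTable, out_dir) -> dict[str, str]:
    """Write the three cohort files; returns a name -> path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.csv",
        "subjects": out / "subjects.csv",
    }
    cohort.counts.to_csv(paths["counts"], sep="\t", index_label="sample_id")
    cohort.samples.to_csv(paths["samples"], index_label="sample_id")
    cohort.subjects.to_csv(paths["subjects"], index_label="subject_id")
    return {k: str(p) for k, p in paths.items()}
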