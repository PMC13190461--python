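"""Filtering, decontamination, the CLR transform, and alpha diversity.

The fixed preprocessing order is: library-size filter -> curated
decontamination -> prevalence filter -> (per analysis) pseudocount + CLR.
Each filter can append a JSON-serializable provenance record describing what
it removed.

The centered log-ratio (CLR) transform of a positive composition x with D
parts is ln(x_i / g(x)) where g(x) is the geometric mean; the output sums to
zero and is invariant to rescaling of x. Zeros are handled by adding a
pseudocount (default 0.65) on the count scale before taking logs: an offset
of that size on the relative-abundance scale would swamp the data, and 0.65
sits inside the conventional count-scale range (0.5-1.0).

Two within-fold modes are provided. ``per_sample`` divides every sample by
its own geometric mean (the standard reading; no fitted state, hence
trivially leakage-free). ``train_anchored`` replaces the denominator by a
constant derived from training samples only — the geometric mean of the
per-taxon mean log pseudocounted counts — matching a training-derived-
denominator reading of within-fold transformation. Both agree whenever all
training samples share one composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .errors import EmptyTableError, ParameterError, StateError

log = logging.getLogger(__name__)

#: Reagent-contaminant genera reported in sequenced negative controls,
#: plus plant-derived chloroplast reads. Matching is exact and
#: case-sensitive after whitespace trimming.
SALTER_GENERA = (
    "Methylobacterium", "Methylorubrum", "Ralstonia", "Mesorhizobium",
    "Microbacterium", "Bradyrhizobium", "Sphingomonas", "Pseudomonas",
    "Acinetobacter",
)
DEFAULT_BLOCKLIST = SALTER_GENERA + ("o__Chloroplast",)


def _record(audit, **kwargs) -> None:
    if audit is not None:
        audit.append(kwargs)
    log.info("filter step: %s", kwargs)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_library_size(cohort: CohortTable, min_reads: int,
                        audit: list | None = None) -> CohortTable:
    """Drop samples whose library size (row sum) is below ``min_reads``.

    Subjects left without samples are dropped from the registry with a
    logged warning.
    """
    if min_reads < 0:
        raise ParameterError("min_reads must be >= 0")
    sizes = cohort.library_sizes
    keep = sizes.index[sizes >= min_reads]
    removed = sorted(set(sizes.index) - set(keep))
    out = cohort.select_samples(keep)
    _record(audit, step="library_size_filter", min_reads=int(min_reads),
            samples_before=cohort.n_samples, samples_after=out.n_samples,
            samples_removed=removed)
    return out


def remove_curated_contaminants(cohort: CohortTable,
                                blocklist=DEFAULT_BLOCKLIST,
                                audit: list | None = None) -> CohortTable:
    """Drop taxa whose trimmed name appears in the curated blocklist.

    Blocklist names absent from the table are logged, not errors.
    """
    block = {str(b).strip() for b in blocklist}
    removed = [t for t in cohort.taxa if str(t).strip() in block]
    missing = sorted(block - {str(t).strip() for t in cohort.taxa})
    if missing:
        log.info("blocklist name(s) not present in table: %s", missing)
    out = cohort.select_taxa([t for t in cohort.taxa if t not in set(removed)])
    _record(audit, step="curated_decontamination",
            taxa_before=cohort.n_taxa, taxa_after=out.n_taxa,
            taxa_removed=removed)
    return out


def prevalence_filter(cohort: CohortTable, min_prev: float,
                      audit: list | None = None) -> CohortTable:
    """Keep taxa present (count > 0) in at least ``min_prev`` of samples.

    The threshold is inclusive: prevalence == min_prev is kept. Column order
    is preserved.
    """
    if not 0 <= min_prev <= 1:
        raise ParameterError("min_prev must be in [0, 1]")
    prev = (cohort.counts > 0).mean(axis=0)
    kept = [t for t in cohort.taxa if prev[t] >= min_prev]
    if not kept:
        raise EmptyTableError("prevalence filter removed every taxon")
    removed = [t for t in cohort.taxa if t not in set(kept)]
    out = cohort.select_taxa(kept)
    _record(audit, step="prevalence_filter", min_prev=float(min_prev),
            taxa_before=cohort.n_taxa, taxa_after=out.n_taxa,
            taxa_removed=removed)
    return out


def preprocess_cohort(cohort: CohortTable, config,
                      blocklist=DEFAULT_BLOCKLIST) -> tuple[CohortTable, list]:
    """Run the fixed filter pipeline; returns (cohort, provenance records)."""
    audit: list = []
    out = filter_library_size(cohort, config.min_library, audit)
    out = remove_curated_contaminants(out, blocklist, audit)
    out = prevalence_filter(out, config.min_prevalence, audit)
    return out, audit


# ---------------------------------------------------------------------------
# Frequency-based contaminant scoring
# ---------------------------------------------------------------------------

def frequency_contaminant_scores(cohort: CohortTable) -> pd.Series:
    """Score each taxon for reagent-contaminant behaviour.

    Reagent contaminants contribute a roughly fixed number of reads per
    sample, so their relative frequency varies inversely with input DNA
    concentration. For each taxon, among the samples where it is present,
    log10(frequency) is fit against log10(concentration) under a contaminant
    model (slope fixed at -1, free intercept) and a non-contaminant model
    (slope 0, free intercept); both have one free parameter, and the residual
    sum-of-squares ratio RSS0/RSS1 is referred to an F(n-1, n-1) tail.
    Smaller p means more contaminant-like. Taxa present in fewer than two
    samples get p = 1.

    This is a deliberately simple frequency test; it is exposed behind this
    single function so a different scorer can be swapped in.
    """
    if "dna_concentration" not in cohort.samples.columns:
        raise ParameterError("dna_concentration is required for frequency scoring")
    conc = pd.to_numeric(cohort.samples["dna_concentration"], errors="coerce")
    ok = conc.notna() & (conc > 0)
    if ok.sum() < 10:
        raise ParameterError(
            "frequency scoring needs dna_concentration for >= 10 samples")

    counts = cohort.counts.loc[ok.index[ok]]
    freq = counts.div(counts.sum(axis=1), axis=0)
    logc = np.log10(conc[ok])

    pvals = {}
    for taxon in cohort.taxa:
        present = freq[taxon] > 0
        n = int(present.sum())
        if n < 2:
            pvals[taxon] = 1.0
            continue
        y = np.log10(freq.loc[present, taxon].to_numpy(dtype=float))
        x = logc[present].to_numpy(dtype=float)
        # contaminant: y = -x + b  ->  residuals of (y + x) about its mean
        rss1 = float(np.sum((y + x - np.mean(y + x)) ** 2))
        # non-contaminant: y = b
        rss0 = float(np.sum((y - np.mean(y)) ** 2))
        if rss1 <= 0.0:
            pvals[taxon] = 0.0 if rss0 > 0 else 1.0
            continue
        pvals[taxon] = float(stats.f.sf(rss0 / rss1, n - 1, n - 1))
    return pd.Series(pvals, name="contaminant_p").loc[cohort.taxa]


# ---------------------------------------------------------------------------
# CLR transform
# ---------------------------------------------------------------------------

def clr_transform(counts_row, pseudocount: float) -> np.ndarray:
    """CLR of a single count vector after adding ``pseudocount``.

    Returns ln((c_i + pseudocount) / g) with g the geometric mean of the
    pseudocounted vector; the output sums to zero (within 1e-9).
    """
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be > 0")
    x = np.asarray(counts_row, dtype=float) + pseudocount
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("CLR needs a vector with at least 2 parts")
    logs = np.log(x)
    return logs - logs.mean()


def clr_matrix(counts, pseudocount: float) -> np.ndarray:
    """Row-wise per-sample CLR of a samples x taxa count matrix."""
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be > 0")
    x = np.asarray(counts, dtype=float) + pseudocount
    if x.ndim != 2 or x.shape[1] < 2:
        raise ParameterError("CLR needs at least 2 taxa")
    logs = np.log(x)
    return logs - logs.mean(axis=1, keepdims=True)


@dataclass
class ClrFitState:
    """Fitted state of the within-fold CLR transform."""

    mode: str
    pseudocount: float
    reference_log_means: np.ndarray | None = None  # train_anchored only

    def __post_init__(self) -> None:
        if self.mode not in ("per_sample", "train_anchored"):
            raise ParameterError(f"unknown CLR mode {self.mode!r}")
        if (self.mode == "train_anchored") != (self.reference_log_means is not None):
            raise StateError(
                "reference_log_means present iff mode == train_anchored")


def fit_clr(train_counts, pseudocount: float, mode: str = "per_sample") -> ClrFitState:
    """Fit the CLR state on training samples only.

    ``per_sample`` has no state to fit. ``train_anchored`` stores the
    per-taxon mean of log pseudocounted counts over the training samples.
    """
    if mode == "per_sample":
        return ClrFitState(mode=mode, pseudocount=pseudocount)
    x = np.asarray(train_counts, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ParameterError("train_anchored fit needs a non-empty matrix")
    ref = np.log(x + pseudocount).mean(axis=0)
    return ClrFitState(mode=mode, pseudocount=pseudocount,
                       reference_log_means=ref)


def apply_clr(state: ClrFitState, counts) -> np.ndarray:
    """Transform a samples x taxa count matrix under a fitted state."""
    x = np.asarray(counts, dtype=float)
    if state.mode == "per_sample":
        return clr_matrix(x, state.pseudocount)
    if state.reference_log_means is None:
        raise StateError("train_anchored apply before fit")
    logs = np.log(x + state.pseudocount)
    return logs - state.reference_log_means.mean()


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon_diversity(counts_row) -> float:
    """Shannon index -sum p_i ln p_i over taxa with p_i > 0 (natural log),
    computed from untransformed relative abundances."""
    x = np.asarray(counts_row, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ParameterError("Shannon diversity is undefined for an all-zero row")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_matrix(counts) -> np.ndarray:
    """Row-wise Shannon diversity of a samples x taxa count matrix."""
    x = np.asarray(counts, dtype=float)
    totals = x.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ParameterError("Shannon diversity is undefined for an all-zero row")
    p = x / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)
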