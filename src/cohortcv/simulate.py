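"""Synthetic longitudinal vaginal-microbiome cohorts.

The generator emulates the processed-data level of a small pregnancy cohort:
~43 subjects with 14/43 preterm prevalence, 1-6 samples each (term mean 3.0,
preterm mean 1.7 — earlier delivery interrupts follow-up), ~110 samples,
~49 genera, library sizes of a few tens of thousands of reads floored at
3,000, and two community states (a Lactobacillus-dominant state tuned near
82% median dominance, and a dysbiotic state with mass spread over several
anaerobe-like genera, ~24% of subjects).

Counts are drawn multinomially from softmax(state baseline + subject effect
+ outcome x planted log-fold-changes + sample noise); the subject effect
vector is drawn once per subject and shared by all of that subject's
samples, which is exactly the repeated-measures structure that makes
sample-level cross-validation leak. Clinical covariates are drawn per a
configurable generative spec whose defaults reproduce the cohort's group
contrasts (wider BMI distribution and more membrane-rupture events under
preterm birth, etc.).

Same seed and parameters always give a byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .cohort import CohortTable
from .errors import ParameterError

# Genus names used by the generator; the first is the dominant-state taxon,
# the next five carry the dysbiotic state's mass. These are field-typical
# labels, not claims about real taxa.
_NAMED_TAXA = (
    "Lactobacillus", "Gardnerella", "Prevotella", "Atopobium", "Sneathia",
    "Anaerococcus", "Mycoplasma", "Peptostreptococcus", "Ureaplasma",
    "Megasphaera", "Dialister", "Finegoldia", "Streptococcus",
    "Staphylococcus", "Bifidobacterium", "Corynebacterium",
)


def default_taxa(n_taxa: int) -> list[str]:
    names = list(_NAMED_TAXA[:n_taxa])
    names += [f"Genus_{i:02d}" for i in range(len(names) + 1, n_taxa + 1)]
    return names


@dataclass
class ClinicalEffect:
    """Generative spec for one clinical covariate.

    kind ``normal``: params are (mean, sd) per group.
    kind ``bernoulli``: params are the event probability per group.
    """

    kind: str
    term: tuple | float
    ptb: tuple | float


#: Defaults reproduce the cohort's published group contrasts (means +- SD or
#: event rates per outcome group).
DEFAULT_CLINICAL_EFFECTS: dict[str, ClinicalEffect] = {
    "maternal_age": ClinicalEffect("normal", (24.2, 4.9), (25.2, 7.3)),
    "prepregnancy_bmi": ClinicalEffect("normal", (23.9, 3.5), (25.6, 5.6)),
    "hemoglobin": ClinicalEffect("normal", (11.5, 0.7), (11.8, 0.9)),
    "pprom": ClinicalEffect("bernoulli", 0.0, 0.214),
    "preeclampsia": ClinicalEffect("bernoulli", 0.0, 0.071),
    "first_trimester_bleeding": ClinicalEffect("bernoulli", 0.276, 0.071),
    "oligohydramnios": ClinicalEffect("bernoulli", 0.034, 0.143),
    "iugr": ClinicalEffect("bernoulli", 0.0, 0.071),
    "gestational_diabetes": ClinicalEffect("bernoulli", 0.0, 0.0),
}

#: Covariate type declarations consumed by the clinical screening module.
DEFAULT_COVARIATE_TYPES: dict[str, str] = {
    "maternal_age": "continuous",
    "prepregnancy_bmi": "continuous",
    "hemoglobin": "continuous",
    "gestational_age_weeks": "continuous",
    "bmi_category": "categorical",
    "pprom": "categorical",
    "preeclampsia": "categorical",
    "first_trimester_bleeding": "categorical",
    "oligohydramnios": "categorical",
    "iugr": "categorical",
    "gestational_diabetes": "categorical",
}

_TRIMESTER_RANGES = ((8.0, 13.9), (14.0, 27.9), (28.0, 38.0))


@dataclass
class CohortParams:
    """Generator settings; the defaults are the study conditions."""

    n_subjects: int = 43
    n_ptb: int = 14
    mean_samples_term: float = 3.0
    mean_samples_ptb: float = 1.7
    max_samples: int = 6
    trimester_weights: tuple = (0.427, 0.400, 0.173)
    n_taxa: int = 49
    frac_dysbiotic: float = 0.24
    subject_effect_sd: float = 1.0
    sample_noise_sd: float = 0.5
    planted_effects: dict[str, float] = field(
        default_factory=lambda: {"Mycoplasma": 1.0})
    library_size_log_mean: float = float(np.log(30000.0))
    library_size_log_sd: float = 0.5
    min_library: int = 3000
    contaminant_taxa: tuple = ()
    contaminant_scale: float = 0.5
    clinical_effects: dict[str, ClinicalEffect] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS))
    early_outlier: bool = False
    outcome_linked_sampling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ptb > self.n_subjects:
            raise ParameterError("n_ptb cannot exceed n_subjects")
        if self.n_ptb < 0 or self.n_subjects <= 0:
            raise ParameterError("subject counts must be non-negative")
        w = np.asarray(self.trimester_weights, dtype=float)
        if w.size != 3 or not np.isclose(w.sum(), 1.0):
            raise ParameterError("trimester_weights must be 3 probabilities summing to 1")
        if not 0 <= self.frac_dysbiotic <= 1:
            raise ParameterError("frac_dysbiotic must be in [0, 1]")
        if self.max_samples < 1:
            raise ParameterError("max_samples must be >= 1")

    def replace(self, **kwargs) -> "CohortParams":
        return dataclasses.replace(self, **kwargs)


def null_params(**overrides) -> CohortParams:
    """Parameters for a fully null cohort: no planted taxa, clinical
    covariates drawn identically in both groups, and sampling structure
    independent of outcome. Used for calibration of the pipeline."""
    effects = {name: ClinicalEffect(e.kind, e.term, e.term)
               for name, e in DEFAULT_CLINICAL_EFFECTS.items()}
    params = CohortParams(planted_effects={}, clinical_effects=effects,
                          mean_samples_ptb=3.0, outcome_linked_sampling=False)
    return params.replace(**overrides) if overrides else params


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _state_baselines(params: CohortParams, rng: np.random.Generator) -> np.ndarray:
    """Two log-scale baseline vectors: index 0 Lactobacillus-dominant
    (realized median dominance ~0.82), index 1 dysbiotic (mass spread over
    up to 5 anaerobe-like taxa)."""
    d = params.n_taxa
    base = rng.normal(0.0, 1.0, size=d)

    # noise-free expected share 0.93; subject effects and sample noise pull
    # the realized median dominance down to ~0.82
    dominant = base.copy()
    others = np.exp(dominant[1:]).sum()
    dominant[0] = np.log(others * 0.93 / 0.07)

    dysbiotic = base.copy()
    n_anaerobe = min(5, d - 1)
    dysbiotic[1:1 + n_anaerobe] = rng.normal(2.5, 0.5, size=n_anaerobe)
    others = np.exp(dysbiotic[1:]).sum()
    dysbiotic[0] = np.log(others * 0.15 / 0.85)
    return np.vstack([dominant, dysbiotic])


def _draw_n_samples(mean: float, max_samples: int,
                    rng: np.random.Generator) -> int:
    """1 + Poisson(mean - 1), redrawn until <= max_samples."""
    lam = max(mean - 1.0, 0.0)
    for _ in range(1000):
        n = 1 + int(rng.poisson(lam))
        if n <= max_samples:
            return n
    return max_samples


def _draw_ga(weights, rng: np.random.Generator, upper: float | None) -> float:
    """Gestational age at collection: trimester by weight, uniform within;
    optionally truncated below ``upper`` (the subject's delivery age)."""
    for _ in range(200):
        tri = rng.choice(3, p=np.asarray(weights, dtype=float))
        lo, hi = _TRIMESTER_RANGES[tri]
        ga = float(rng.uniform(lo, hi))
        if upper is None or ga < upper:
            return ga
    lo = _TRIMESTER_RANGES[0][0]
    return float(rng.uniform(lo, upper - 0.1))  # fallback for early deliveries


def _draw_clinical(effect: ClinicalEffect, is_ptb: bool,
                   rng: np.random.Generator):
    params = effect.ptb if is_ptb else effect.term
    if effect.kind == "normal":
        mu, sd = params
        return float(rng.normal(mu, sd))
    if effect.kind == "bernoulli":
        return int(rng.random() < float(params))
    raise ParameterError(f"unknown clinical effect kind {effect.kind!r}")


def _bmi_category(bmi: float) -> str:
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def generate_cohort(params: CohortParams, return_truth: bool = False):
    """Generate a cohort; optionally also return the ground truth
    (community states, subject effect vectors, planted effects, deliveries)
    for use as a simulation oracle."""
    taxa = default_taxa(params.n_taxa)
    unknown = set(params.planted_effects) - set(taxa)
    if unknown:
        raise ParameterError(f"planted_effects name unknown taxa: {sorted(unknown)}")

    master = params.seed
    baselines = _state_baselines(params, child_rng(master, "baselines"))
    planted_vec = np.zeros(params.n_taxa)
    for name, lfc in params.planted_effects.items():
        planted_vec[taxa.index(name)] = float(lfc)

    rng_assign = child_rng(master, "assignment")
    subject_ids = [f"P{i + 1:03d}" for i in range(params.n_subjects)]
    ptb_flags = np.zeros(params.n_subjects, dtype=int)
    ptb_flags[rng_assign.choice(params.n_subjects, params.n_ptb,
                                replace=False)] = 1
    states = (rng_assign.random(params.n_subjects)
              < params.frac_dysbiotic).astype(int)

    subj_rows, sample_rows, count_rows, sample_ids = [], [], [], []
    subject_effects = {}
    sample_counter = 0
    outlier_assigned = False

    for i, sid in enumerate(subject_ids):
        is_ptb = bool(ptb_flags[i])
        rng_s = child_rng(master, "subject", i)

        if is_ptb:
            if params.early_outlier and not outlier_assigned:
                delivery = 20.0
                outlier_assigned = True
            else:
                delivery = float(rng_s.uniform(32.0, 36.9))
        else:
            delivery = float(rng_s.uniform(37.0, 41.5))

        mean_n = (params.mean_samples_ptb if is_ptb and params.outcome_linked_sampling
                  else params.mean_samples_term)
        n_samp = _draw_n_samples(mean_n, params.max_samples, rng_s)

        effect = rng_s.normal(0.0, params.subject_effect_sd, params.n_taxa)
        subject_effects[sid] = effect
        eta_base = baselines[states[i]] + effect + (planted_vec if is_ptb else 0.0)

        clinical = {name: _draw_clinical(eff, is_ptb, rng_s)
                    for name, eff in params.clinical_effects.items()}
        if "prepregnancy_bmi" in clinical:
            clinical["bmi_category"] = _bmi_category(clinical["prepregnancy_bmi"])
        subj_rows.append({"subject_id": sid, "outcome": int(is_ptb),
                          "ga_delivery_weeks": round(delivery, 1), **clinical})

        upper = delivery if (is_ptb and params.outcome_linked_sampling) else None
        gas = sorted(_draw_ga(params.trimester_weights, rng_s, upper)
                     for _ in range(n_samp))
        for ga in gas:
            sample_counter += 1
            samp_id = f"S{sample_counter:04d}"
            eta = eta_base + rng_s.normal(0.0, params.sample_noise_sd,
                                          params.n_taxa)
            eta -= eta.max()  # softmax stability
            p = np.exp(eta)
            p /= p.sum()
            lib = int(np.exp(rng_s.normal(params.library_size_log_mean,
                                          params.library_size_log_sd)))
            lib = max(lib, params.min_library)
            count_rows.append(rng_s.multinomial(lib, p))
            sample_rows.append({
                "sample_id": samp_id, "subject_id": sid,
                "gestational_age_weeks": round(ga, 1),
                "dna_concentration": round(float(np.exp(
                    rng_s.normal(np.log(10.0), 0.8))), 3),
            })
            sample_ids.append(samp_id)

    counts = pd.DataFrame(np.asarray(count_rows, dtype=np.int64),
                          index=pd.Index(sample_ids, name="sample_id"),
                          columns=taxa)
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    subjects = pd.DataFrame(subj_rows).set_index("subject_id")
    cohort = CohortTable(counts, samples, subjects,
                         attrs={"seed": params.seed})
    if params.contaminant_taxa:
        cohort = plant_contaminants(cohort, params)
    if not return_truth:
        return cohort
    truth = {
        "states": {sid: int(states[i]) for i, sid in enumerate(subject_ids)},
        "subject_effects": subject_effects,
        "planted_effects": dict(params.planted_effects),
        "deliveries": dict(zip(subjects.index,
                               subjects["ga_delivery_weeks"])),
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# Contaminant planting
# ---------------------------------------------------------------------------

def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        out = np.zeros(weights.size, dtype=np.int64)
        if weights.size:
            out[0] = total
        return out
    ideal = weights * (total / weights.sum())
    base = np.floor(ideal).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:short]] += 1
    return base


def plant_contaminants(cohort: CohortTable, params: CohortParams) -> CohortTable:
    """Inject reagent-like contaminants whose expected relative abundance is
    proportional to 1/DNA concentration; other taxa are rescaled so library
    sizes are unchanged and counts stay non-negative integers."""
    if not params.contaminant_taxa:
        return cohort
    if ("dna_concentration" not in cohort.samples.columns
            or cohort.samples["dna_concentration"].isna().any()):
        raise ParameterError("plant_contaminants requires dna_concentration")

    counts = cohort.counts.copy()
    for name in params.contaminant_taxa:
        if name not in counts.columns:
            counts[name] = 0
    conc = cohort.samples["dna_concentration"].to_numpy(dtype=float)
    contaminants = list(params.contaminant_taxa)
    others = [t for t in counts.columns if t not in set(contaminants)]

    mat = counts.to_numpy(dtype=np.int64)
    cont_idx = [counts.columns.get_loc(t) for t in contaminants]
    other_idx = [counts.columns.get_loc(t) for t in others]
    for r in range(mat.shape[0]):
        lib = int(mat[r].sum())
        frac = np.minimum(params.contaminant_scale / conc[r], 0.8 / len(cont_idx))
        target = np.round(frac * lib).astype(np.int64)
        target = np.full(len(cont_idx), target) if target.ndim == 0 else target
        remaining = lib - int(target.sum())
        mat[r, other_idx] = _largest_remainder(mat[r, other_idx], remaining)
        mat[r, cont_idx] = target

    new_counts = pd.DataFrame(mat, index=counts.index, columns=counts.columns)
    return CohortTable(new_counts, cohort.samples.copy(),
                       cohort.subjects.copy(), dict(cohort.attrs))
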