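"""Clinical feature selection: three strategies, leakage-safe by contract.

``dream_minimal`` uses only gestational age at sampling and maternal age
(the minimal benchmark-style adjustment). ``literature`` uses a fixed list
of ten evidence-based risk factors intersected with the available columns.
``data_driven`` screens every eligible covariate univariately against the
outcome within the training subjects of each fold — Mann-Whitney U for
continuous variables, Fisher's exact test (with exact r x 2 enumeration)
for categorical — ranks by ascending p with an alphabetical tie-break,
takes the top k, and force-includes the mandatory variables by replacing
the lowest-ranked non-mandatory entries.

Screening operates on one row per subject; time-varying covariates are
reduced to the value at the subject's earliest sample. Variables missing in
at least the configured fraction of training subjects are excluded, and
missing values are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .errors import ParameterError

log = logging.getLogger(__name__)

#: The ten literature-based risk factors (order is the reporting order).
LITERATURE_FEATURES = (
    "maternal_age", "prepregnancy_bmi", "hemoglobin",
    "gestational_age_weeks", "gestational_diabetes", "preeclampsia",
    "first_trimester_bleeding", "pprom", "oligohydramnios", "iugr",
)
#: Always-included variables (sampling age + maternal age).
MANDATORY_FEATURES = ("gestational_age_weeks", "maternal_age")


@dataclass
class FeatureStrategySpec:
    kind: str
    literature_list: tuple = LITERATURE_FEATURES
    mandatory: tuple = MANDATORY_FEATURES
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("dream_minimal", "literature", "data_driven"):
            raise ParameterError(f"unknown clinical strategy {self.kind!r}")
        if self.top_k < len(self.mandatory):
            raise ParameterError("top_k must be >= number of mandatory variables")


@dataclass
class UnivariateResult:
    variable: str
    test: str            # "rank_sum" or "fisher_exact"
    p: float
    n_used: int
    flag: str = ""       # "", "zero_variance", "excluded"


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------

def fisher_exact_rx2(table) -> float:
    """Two-sided Fisher's exact test for an r x 2 contingency table.

    Enumerates every table with the observed margins and sums the
    multivariate hypergeometric probabilities of those no more probable
    than the observed table (point-probability rule). For r = 2 this
    reproduces the classical two-sided 2 x 2 test.
    """
    tab = np.asarray(table, dtype=np.int64)
    if tab.ndim != 2 or tab.shape[1] != 2 or (tab < 0).any():
        raise ParameterError("fisher_exact_rx2 expects a non-negative r x 2 table")
    row_sums = tab.sum(axis=1)
    c1 = int(tab[:, 0].sum())
    n_total = int(tab.sum())
    if n_total == 0:
        return 1.0
    denom = comb(n_total, c1)

    def prob(first_col) -> float:
        num = 1
        for r_i, a_i in zip(row_sums, first_col):
            num *= comb(int(r_i), int(a_i))
        return num / denom

    p_obs = prob(tab[:, 0])
    tol = p_obs * (1.0 + 1e-7)
    total = 0.0
    r = len(row_sums)

    def recurse(i: int, remaining: int, acc: list) -> None:
        nonlocal total
        if i == r - 1:
            if 0 <= remaining <= row_sums[i]:
                p = prob(acc + [remaining])
                if p <= tol:
                    total += p
            return
        # bound the branch so remaining mass fits into later rows
        lo = max(0, remaining - int(row_sums[i + 1:].sum()))
        hi = min(int(row_sums[i]), remaining)
        for a in range(lo, hi + 1):
            recurse(i + 1, remaining - a, acc + [a])

    recurse(0, c1, [])
    return min(total, 1.0)


def univariate_assoc(values, outcome, var_type: str) -> UnivariateResult:
    """Association of one subject-level covariate with the binary outcome.

    Continuous -> two-sided Mann-Whitney U (midranks, normal approximation
    with tie correction); categorical -> two-sided Fisher's exact test with
    exact r x 2 enumeration. Missing values are dropped pairwise.
    """
    values = pd.Series(values)
    outcome = np.asarray(outcome)
    name = values.name or "variable"
    ok = values.notna().to_numpy()
    vals, out = values[ok], outcome[ok]
    n_used = int(ok.sum())

    for cls in (0, 1):
        if (out == cls).sum() < 2:
            return UnivariateResult(name, "rank_sum" if var_type == "continuous"
                                    else "fisher_exact", 1.0, n_used, "excluded")
    if vals.nunique() < 2:
        return UnivariateResult(name, "rank_sum" if var_type == "continuous"
                                else "fisher_exact", 1.0, n_used, "zero_variance")

    if var_type == "continuous":
        x = vals[out == 1].to_numpy(dtype=float)
        y = vals[out == 0].to_numpy(dtype=float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        return UnivariateResult(name, "rank_sum", float(res.pvalue), n_used)
    if var_type == "categorical":
        table = pd.crosstab(vals, pd.Series(out, index=vals.index))
        for cls in (0, 1):
            if cls not in table.columns:
                table[cls] = 0
        # columns ordered (case, control) for the r x 2 enumeration
        p = fisher_exact_rx2(table[[1, 0]].to_numpy())
        return UnivariateResult(name, "fisher_exact", float(p), n_used)
    raise ParameterError(f"unknown var_type {var_type!r}")


# ---------------------------------------------------------------------------
# Subject-level screening and strategy dispatch
# ---------------------------------------------------------------------------

def subject_level_view(cohort: CohortTable, subject_ids=None) -> pd.DataFrame:
    """One row per subject: clinical covariates plus the gestational age at
    the subject's earliest sample (the subject-level reduction of the
    sampling-age variable)."""
    subjects = cohort.subjects if subject_ids is None else \
        cohort.subjects.loc[list(subject_ids)]
    first_ga = (cohort.samples
                .groupby("subject_id")["gestational_age_weeks"].min())
    view = subjects.copy()
    view["gestational_age_weeks"] = first_ga.reindex(view.index)
    return view


def infer_var_type(series: pd.Series, declared: dict[str, str] | None) -> str:
    declared = declared or {}
    if series.name in declared:
        return declared[series.name]
    if pd.api.types.is_float_dtype(series):
        return "continuous"
    return "categorical"


def screen_univariate(subject_view: pd.DataFrame,
                      covariate_types: dict[str, str] | None = None,
                      missingness_max: float = 0.30) -> pd.DataFrame:
    """Univariate screening report for every eligible covariate.

    Variables with missingness >= ``missingness_max`` among the given
    subjects are excluded before testing. Returns a DataFrame with columns
    variable, test, p, n_used, flag, rank — ranked by ascending p with
    alphabetical tie-break (a total, deterministic order).
    """
    outcome = subject_view["outcome"].to_numpy(dtype=int)
    rows = []
    for col in subject_view.columns:
        if col in ("outcome", "ga_delivery_weeks"):
            continue
        series = subject_view[col]
        if series.isna().mean() >= missingness_max:
            log.info("screening: excluding %r (missingness %.0f%%)",
                     col, 100 * series.isna().mean())
            continue
        res = univariate_assoc(series.rename(col), outcome,
                               infer_var_type(series, covariate_types))
        rows.append(vars(res))
    report = pd.DataFrame(rows, columns=["variable", "test", "p",
                                         "n_used", "flag"])
    report = report.sort_values(["p", "variable"],
                                kind="stable").reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report


def select_clinical(strategy: FeatureStrategySpec,
                    subject_view: pd.DataFrame,
                    covariate_types: dict[str, str] | None = None,
                    missingness_max: float = 0.30) -> list[str]:
    """Select clinical features per the strategy, on training subjects only.

    Deterministic: identical training partitions give identical selections.
    """
    available = [c for c in subject_view.columns
                 if c not in ("outcome", "ga_delivery_weeks")]
    missing_mand = [m for m in strategy.mandatory if m not in available]
    if missing_mand:
        raise ParameterError(
            f"mandatory variable(s) absent from table: {missing_mand}")

    if strategy.kind == "dream_minimal":
        return list(strategy.mandatory)
    if strategy.kind == "literature":
        return [v for v in strategy.literature_list if v in available]

    report = screen_univariate(subject_view, covariate_types, missingness_max)
    ranked = report["variable"].tolist()
    top = ranked[:strategy.top_k]
    for mand in strategy.mandatory:
        if mand not in top:
            # replace the lowest-ranked non-mandatory entry
            for j in range(len(top) - 1, -1, -1):
                if top[j] not in strategy.mandatory:
                    top[j] = mand
                    break
    order = {v: i for i, v in enumerate(ranked)}
    return sorted(top, key=lambda v: order[v])
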