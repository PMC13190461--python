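"""Covariate-adjusted per-taxon differential abundance on CLR values.

The estimator is an ordinary least-squares fit, per taxon, of
``CLR value ~ intercept + outcome + covariates``; the log-fold-change (LFC)
is the outcome coefficient, p is the two-sided t tail of that coefficient,
and q is the Benjamini-Hochberg adjustment over the tested taxa. Because
every taxon shares one design matrix the fits are vectorized into a single
least-squares solve.

The function signature is the adapter seam: any callable with the same
(clr, outcome, covariates) -> DataFrame contract — e.g. a wrapper around an
external bias-corrected compositional DA tool — can be passed to the nested
cross-validation engine in place of :func:`da_test` for replication studies.
The framework's contribution is where and how DA runs (within training
folds, thresholded at p < 0.10, tallied across folds), not the estimator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

log = logging.getLogger(__name__)

#: Default adjustment covariates for the outcome model.
DEFAULT_DA_COVARIATES = ("maternal_age", "prepregnancy_bmi")


def da_test(clr, outcome, covariates=None, taxa=None) -> pd.DataFrame:
    """Per-taxon covariate-adjusted linear-model differential abundance.

    Parameters
    ----------
    clr : (n_samples, n_taxa) array or DataFrame of CLR values.
    outcome : length-n binary vector (PTB=1) per sample.
    covariates : optional (n_samples, n_cov) array/DataFrame of numeric
        adjustment covariates; rows with missing covariates are dropped
        (logged).
    taxa : taxon names; taken from the DataFrame columns when omitted.

    Returns a DataFrame with columns taxon, lfc, p, q sorted by p.
    """
    if isinstance(clr, pd.DataFrame):
        taxa = list(clr.columns) if taxa is None else list(taxa)
        clr = clr.to_numpy(dtype=float)
    else:
        clr = np.asarray(clr, dtype=float)
        taxa = [f"taxon_{j}" for j in range(clr.shape[1])] if taxa is None else list(taxa)
    y = np.asarray(outcome, dtype=float)

    if covariates is None:
        cov = np.empty((len(y), 0))
    elif isinstance(covariates, pd.DataFrame):
        cov = covariates.to_numpy(dtype=float)
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]

    keep = ~np.isnan(cov).any(axis=1) if cov.shape[1] else np.ones(len(y), bool)
    if not keep.all():
        log.info("da_test: dropping %d sample(s) with missing covariates",
                 int((~keep).sum()))
        clr, y, cov = clr[keep], y[keep], cov[keep]

    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ParameterError("da_test requires both outcome classes")
    if counts.min() < 3:
        raise ParameterError("da_test requires >= 3 samples per outcome class")

    X = np.column_stack([np.ones(len(y)), y, cov])
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        log.warning("da_test: rank-deficient design (rank %d < %d); "
                    "returning NA statistics", rank, k)
        return pd.DataFrame({"taxon": taxa, "lfc": np.nan,
                             "p": np.nan, "q": np.nan})

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ clr            # (k, n_taxa)
    resid = clr - X @ beta
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    lfc = beta[1]
    with np.errstate(invalid="ignore"):
        tval = lfc / se
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"taxon": taxa, "lfc": lfc, "p": p, "q": q})
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def within_fold_da_select(clr_train, outcome_train, covariates=None,
                          threshold: float = 0.10, taxa=None) -> list[str]:
    """Taxa with p < ``threshold`` from :func:`da_test` on training samples
    only. Callers must never pass held-out samples; the selection is a pure
    function of the training partition. May return an empty list (logged) —
    the model then runs on clinical features plus Shannon diversity alone."""
    if threshold <= 0:
        return []
    res = da_test(clr_train, outcome_train, covariates=covariates, taxa=taxa)
    selected = res.loc[res["p"] < threshold, "taxon"].tolist()
    if not selected:
        log.info("within-fold DA selected no taxa at p < %.3g", threshold)
    return selected


def da_stability(per_fold_selections, per_fold_lfc_signs) -> pd.DataFrame:
    """Cross-fold detection-frequency tally.

    Parameters
    ----------
    per_fold_selections : list (one entry per fold) of selected taxon lists.
    per_fold_lfc_signs : list of {taxon: sign} maps for the selecting folds.

    Returns a DataFrame (taxon, detection_count, direction_consistent)
    sorted by detection count descending. ``direction_consistent`` is True
    iff every fold that selected the taxon agrees on the LFC sign.
    """
    all_taxa = sorted({t for sel in per_fold_selections for t in sel})
    rows = []
    for taxon in all_taxa:
        count = sum(taxon in sel for sel in per_fold_selections)
        signs = {np.sign(signs[taxon])
                 for sel, signs in zip(per_fold_selections, per_fold_lfc_signs)
                 if taxon in sel and taxon in signs}
        rows.append({"taxon": taxon, "detection_count": int(count),
                     "direction_consistent": len(signs) <= 1})
    out = pd.DataFrame(rows, columns=["taxon", "detection_count",
                                      "direction_consistent"])
    return out.sort_values(["detection_count", "taxon"],
                           ascending=[False, True],
                           kind="stable").reset_index(drop=True)
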