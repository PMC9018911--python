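"""Lifespan trends in structure-function coupling.

Coupling magnitude (the maximum regional or global R2) and optimal-
predictor prevalence are correlated with age after residualising nuisance
variables: sex, time of visit, number of retained frames, mean framewise
displacement, total connectome weight and binary density, plus each node's
binary and weighted degree for regional analyses.  Both the coupling
measure and age are projected off the covariates before correlating, so the
result equals the partial correlation controlling the same covariates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .nulls import bh_fdr
from .regression import best_predictor, global_coupling, regional_coupling

__all__ = [
    "GLOBAL_COVARIATES",
    "cohort_coupling_summary",
    "residualize",
    "age_correlation",
    "prevalence_trend",
    "regional_age_map",
    "age_binned_analysis",
]

GLOBAL_COVARIATES = ("sex", "visit_time", "n_frames", "mean_fd",
                     "total_weight", "binary_density")


def cohort_coupling_summary(cohort):
    """Per-subject coupling statistics for a cohort with predictor stacks.

    Returns ``(global_max_r2, best_labels, max_r2)``: the best global
    edge-wise R2 per subject, the optimal predictor label per subject x
    region, and the corresponding maximum regional R2.
    """
    n_sub = cohort.n_subjects
    n = cohort.geometry.n_parcels
    gmax = np.empty(n_sub)
    best = np.empty((n_sub, n), dtype=object)
    max_r2 = np.empty((n_sub, n))
    for s in range(n_sub):
        stack = cohort.stacks[s]
        if stack is None:
            raise ValueError("cohort was generated without predictor stacks")
        r2g, _ = global_coupling(cohort.fc[s], stack)
        gmax[s] = np.nanmax(r2g)
        r2r, _ = regional_coupling(cohort.fc[s], stack)
        best[s], max_r2[s] = best_predictor(r2r, stack.labels)
    return gmax, best, max_r2


def residualize(values: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of ``values`` on ``covariates`` plus an intercept.

    Covariate columns are z-scored for conditioning (this does not change
    the residual span); collinear columns are tolerated via minimum-norm
    least squares with a warning.
    """
    y = np.asarray(values, dtype=float)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    sd = x.std(axis=0)
    # treat float-noise-constant columns (e.g. a fixed density) as constant
    keep = sd > 1e-10 * (np.abs(x).max(axis=0) + 1.0)
    xz = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    design = np.column_stack([np.ones(len(y)), xz])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn("collinear covariates; residualising on their span")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def age_correlation(residuals: np.ndarray, age: np.ndarray):
    """Pearson correlation of residualised values with age, with the
    two-sided t-based p-value."""
    residuals = np.asarray(residuals, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(residuals) < 10:
        raise ValueError("need at least 10 subjects")
    if np.std(residuals) == 0 or np.std(age) == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(residuals, age)
    return float(res.statistic), float(res.pvalue)


def _partial_age_corr(values: np.ndarray, age: np.ndarray,
                      covariates: np.ndarray):
    """Residualise both sides on the covariates, then correlate."""
    rv = residualize(values, covariates)
    ra = residualize(age, covariates)
    return age_correlation(rv, ra)


def prevalence_trend(best_labels: np.ndarray, labels: list[str],
                     age: np.ndarray, covariates: np.ndarray,
                     q: float = 0.05) -> pd.DataFrame:
    """Age trend of each predictor's prevalence as the optimal regional
    model.

    ``best_labels`` has shape (n_subjects, n_regions).  For each subject
    the fraction of regions best explained by each predictor is computed
    (rows sum to 1), residualised against the nuisance covariates, and
    correlated with (residualised) age; Benjamini-Hochberg controls the FDR
    across predictors.  Predictors with constant prevalence are reported
    with NaN statistics.
    """
    best_labels = np.asarray(best_labels, dtype=object)
    n_sub = best_labels.shape[0]
    idx = {lbl: k for k, lbl in enumerate(labels)}
    frac = np.zeros((n_sub, len(labels)))
    for s in range(n_sub):
        for lbl in best_labels[s]:
            frac[s, idx[lbl]] += 1
    frac /= best_labels.shape[1]

    r = np.full(len(labels), np.nan)
    p = np.full(len(labels), np.nan)
    for k in range(len(labels)):
        if np.std(frac[:, k]) == 0:
            continue
        r[k], p[k] = _partial_age_corr(frac[:, k], age, covariates)
    tested = np.isfinite(p)
    reject = np.zeros(len(labels), dtype=bool)
    if tested.any():
        _, reject[tested] = bh_fdr(p[tested], q)
    return pd.DataFrame({"predictor": labels, "r": r, "p": p,
                         "significant": reject,
                         "mean_fraction": frac.mean(axis=0)})


def regional_age_map(max_r2: np.ndarray, age: np.ndarray,
                     covariates: np.ndarray,
                     node_degrees: np.ndarray | None = None) -> np.ndarray:
    """Per-region partial correlation of coupling magnitude with age.

    ``max_r2`` has shape (n_subjects, n_regions).  ``node_degrees`` holds
    per-region additional covariates of shape (n_subjects, n_regions, k),
    e.g. each node's binary and weighted degree, appended to the global
    covariate set for that region's correlation.
    """
    max_r2 = np.asarray(max_r2, dtype=float)
    n_reg = max_r2.shape[1]
    out = np.empty(n_reg)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != max_r2.shape[0]:
        cov = cov.T
    for i in range(n_reg):
        c = cov
        if node_degrees is not None:
            c = np.column_stack([cov, node_degrees[:, i, :]])
        out[i], _ = _partial_age_corr(max_r2[:, i], age, c)
    return out


def age_binned_analysis(age: np.ndarray, values: np.ndarray,
                        n_bins: int = 10, min_per_bin: int = 3):
    """Equal-count age binning of a per-subject summary.

    Returns ``(table, spearman_r)``: per-bin median age, subject count and
    mean value, plus the Spearman correlation of bin medians with bin
    means.  ``values`` may be a vector or a (n_subjects, k) matrix, in
    which case per-bin means are taken column-wise and the trend uses the
    first column.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    age = np.asarray(age, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(age, kind="stable")
    splits = np.array_split(order, n_bins)
    if min(len(s) for s in splits) < min_per_bin:
        raise ValueError(f"bins would contain fewer than {min_per_bin} subjects")
    rows = []
    for b, idx in enumerate(splits):
        v = values[idx]
        rows.append({
            "bin": b,
            "median_age": float(np.median(age[idx])),
            "n_subjects": len(idx),
            "mean_value": float(np.mean(v if v.ndim == 1 else v[:, 0])),
        })
    table = pd.DataFrame(rows)
    res = stats.spearmanr(table["median_age"], table["mean_value"])
    return table, float(res.statistic)
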