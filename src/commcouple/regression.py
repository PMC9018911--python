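"""Structure-function coupling regressions.

All coupling statistics are in-sample ordinary least squares fits of
functional connectivity (FC) values on one or more predictor matrices:
globally over the vectorised upper triangle, regionally over single rows
(excluding the self-connection), stratified by hop distance, restricted to
direct structural connections, or with two or all forty predictors at once.
R-squared is ``1 - SS_res / SS_tot``; the two-predictor improvement is
reported on the adjusted scale
``R2_adj = 1 - (1 - R2) (N - 1) / (N - p - 1)`` where p counts slopes plus
the intercept.

Pairs whose predictor value is non-finite (failed navigation routes) are
dropped from each fit, and the number of samples actually used is recorded.
Fits with fewer than ``MIN_SAMPLES`` finite pairs return NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import ConnectivityMatrix
from .predictors import PredictorStack, hop_distance

__all__ = [
    "simple_fit",
    "adjusted_r2",
    "global_coupling",
    "hop_decomposition",
    "regional_coupling",
    "best_predictor",
    "greedy_pair_fit",
    "pair_counts",
    "full_model_fit",
    "pca_predictor_fit",
    "sc_direct_fit",
    "optimal_frequency",
    "predictor_embedding",
    "PairCountMatrix",
]

MIN_SAMPLES = 10


@dataclass
class PairCountMatrix:
    """Symmetric counts of how often unordered predictor pairs were selected
    together by the greedy two-predictor search."""

    counts: np.ndarray
    labels: list[str]

    @property
    def total_selections(self) -> int:
        return int(self.counts.sum() // 2)


def simple_fit(y: np.ndarray, x: np.ndarray):
    """OLS of y on x with intercept; returns ``(r2, intercept, slope)``.

    Pairs with non-finite x are dropped.  Returns NaNs when fewer than
    ``MIN_SAMPLES`` finite pairs remain; raises on zero-variance inputs.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    xm, ym = x[mask], y[mask]
    n = len(xm)
    if n < MIN_SAMPLES:
        return np.nan, np.nan, np.nan
    if np.ptp(xm) == 0:
        raise ValueError("zero-variance predictor")
    if np.ptp(ym) == 0:
        raise ValueError("zero-variance response")
    xc = xm - xm.mean()
    yc = ym - ym.mean()
    slope = (xc @ yc) / (xc @ xc)
    intercept = ym.mean() - slope * xm.mean()
    ss_res = ((yc - slope * xc) ** 2).sum()
    ss_tot = (yc ** 2).sum()
    return 1.0 - ss_res / ss_tot, intercept, slope


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Sample-size/complexity adjusted R2:
    ``1 - (1 - R2) (N - 1) / (N - p - 1)``; p counts slopes plus intercept."""
    if n <= p + 1:
        raise ValueError(f"adjusted R2 requires n > p + 1 (got n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _r2_masked(y: np.ndarray, x: np.ndarray):
    """Simple-fit r2 plus sample count, NaN-safe for degenerate inputs."""
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < MIN_SAMPLES:
        return np.nan, n
    xm, ym = x[mask], y[mask]
    sx = xm.std()
    sy = ym.std()
    if sx == 0 or sy == 0:
        return np.nan, n
    r = ((xm - xm.mean()) @ (ym - ym.mean())) / (n * sx * sy)
    return r * r, n


def global_coupling(fc: ConnectivityMatrix, stack: PredictorStack):
    """Edge-wise variance in FC explained by each predictor over the
    vectorised upper triangle.  Returns ``(r2 array, n_used array)``."""
    n = fc.n_nodes
    iu = np.triu_indices(n, 1)
    y = fc.values[iu]
    r2 = np.empty(len(stack))
    n_used = np.empty(len(stack), dtype=int)
    for k, mat in enumerate(stack.matrices):
        r2[k], n_used[k] = _r2_masked(y, mat[iu])
    return r2, n_used


def hop_decomposition(fc: ConnectivityMatrix, stack: PredictorStack,
                      sc: ConnectivityMatrix):
    """Edge-wise fits stratified by binary shortest-path hop count.

    Returns ``(hops, r2)`` where ``hops`` lists the strata (1 = directly
    connected pairs) and ``r2`` has shape (n_strata, n_predictors); strata
    with fewer than ``MIN_SAMPLES`` pairs are NaN.
    """
    n = fc.n_nodes
    iu = np.triu_indices(n, 1)
    hop = hop_distance(sc)[iu].astype(int)
    y = fc.values[iu]
    strata = np.unique(hop)
    r2 = np.full((len(strata), len(stack)), np.nan)
    for si, h in enumerate(strata):
        m = hop == h
        for k, mat in enumerate(stack.matrices):
            r2[si, k], _ = _r2_masked(y[m], mat[iu][m])
    return strata, r2


def regional_coupling(fc: ConnectivityMatrix, stack: PredictorStack):
    """Per-region fits: FC row i (self-connection excluded) on the same row
    of each predictor.  Returns ``(r2, n_used)`` of shape (N, n_pred)."""
    n = fc.n_nodes
    p = len(stack)
    r2 = np.empty((n, p))
    n_used = np.empty((n, p), dtype=int)
    keep = ~np.eye(n, dtype=bool)
    for i in range(n):
        y = fc.values[i, keep[i]]
        for k, mat in enumerate(stack.matrices):
            r2[i, k], n_used[i, k] = _r2_masked(y, mat[i, keep[i]])
    return r2, n_used


def best_predictor(r2: np.ndarray, labels: list[str]):
    """Per-region argmax predictor; exact ties resolve to the earlier
    battery label.  Returns ``(best label array, best r2 array)``."""
    r2 = np.asarray(r2, dtype=float)
    filled = np.where(np.isfinite(r2), r2, -np.inf)
    if np.any(~np.isfinite(filled).any(axis=1)):
        raise ValueError("region with no finite fit")
    idx = np.argmax(filled, axis=1)  # argmax takes the first maximum
    return np.asarray(labels, dtype=object)[idx], filled[np.arange(len(idx)), idx]


def _ols_r2(y: np.ndarray, design: np.ndarray) -> float:
    """Minimum-norm least squares R2 with intercept."""
    n = len(y)
    x = np.column_stack([np.ones(n), design])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return np.nan
    return 1.0 - (resid ** 2).sum() / ss_tot


def greedy_pair_fit(fc_row: np.ndarray, stack_rows: np.ndarray):
    """Greedy two-predictor selection for one region.

    Picks the best single predictor by R2, then the second predictor whose
    inclusion in the two-slope model maximises R2.  Returns a dict with the
    selected indices, both R2 values, and the adjusted-R2 improvement
    ``delta_adj = R2_adj(pair, p=3) - R2_adj(single, p=2)``.
    """
    p = stack_rows.shape[0]
    r2_single = np.full(p, np.nan)
    for k in range(p):
        r2_single[k], _ = _r2_masked(fc_row, stack_rows[k])
    if not np.any(np.isfinite(r2_single)):
        raise ValueError("no predictor admits a fit for this region")
    best = int(np.nanargmax(r2_single))
    r2_1 = r2_single[best]

    best_second, r2_2 = -1, -np.inf
    n_pair_used = 0
    for k in range(p):
        if k == best:
            continue
        mask = np.isfinite(fc_row) & np.isfinite(stack_rows[best]) & np.isfinite(stack_rows[k])
        if mask.sum() < MIN_SAMPLES:
            continue
        r2k = _ols_r2(fc_row[mask], np.column_stack([stack_rows[best][mask],
                                                     stack_rows[k][mask]]))
        if r2k > r2_2:
            r2_2, best_second, n_pair_used = r2k, k, int(mask.sum())
    mask1 = np.isfinite(fc_row) & np.isfinite(stack_rows[best])
    n1 = int(mask1.sum())
    delta = adjusted_r2(r2_2, n_pair_used, 3) - adjusted_r2(r2_1, n1, 2)
    return {
        "best": best,
        "second": best_second,
        "r2_single": r2_1,
        "r2_pair": r2_2,
        "delta_r2_adj": delta,
        "n_used": n_pair_used,
    }


def pair_counts(selections, n_predictors: int, labels: list[str] | None = None) -> PairCountMatrix:
    """Count how frequently each unordered predictor pair was selected.

    ``selections`` is an iterable of (first, second) index pairs over
    subjects x regions.
    """
    counts = np.zeros((n_predictors, n_predictors), dtype=int)
    for a, b in selections:
        if a == b:
            raise ValueError("pair selection must name two distinct predictors")
        counts[a, b] += 1
        counts[b, a] += 1
    if labels is None:
        labels = [str(i) for i in range(n_predictors)]
    return PairCountMatrix(counts=counts, labels=list(labels))


def full_model_fit(fc_row: np.ndarray, stack_rows: np.ndarray):
    """OLS of one FC row on all predictors with finite rows jointly.

    Predictor rows containing non-finite entries (on the finite-FC support)
    are dropped; near-collinear designs are handled by minimum-norm least
    squares.  Returns ``(r2, kept predictor indices)``.
    """
    base = np.isfinite(fc_row)
    kept = [k for k in range(stack_rows.shape[0])
            if np.all(np.isfinite(stack_rows[k][base]))]
    if not kept:
        raise ValueError("no finite-complete predictors for this region")
    y = fc_row[base]
    design = stack_rows[np.array(kept)][:, base].T
    return _ols_r2(y, design), kept


def pca_predictor_fit(fc_row: np.ndarray, stack_rows: np.ndarray, k: int):
    """OLS of one FC row on the top-k principal components of the
    (column-standardised) predictor design."""
    base = np.isfinite(fc_row)
    kept = [j for j in range(stack_rows.shape[0])
            if np.all(np.isfinite(stack_rows[j][base]))]
    design = stack_rows[np.array(kept)][:, base].T
    if k > design.shape[1]:
        raise ValueError(f"k={k} exceeds {design.shape[1]} usable predictors")
    mu = design.mean(axis=0)
    sd = design.std(axis=0)
    sd[sd == 0] = 1.0
    z = (design - mu) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    return _ols_r2(fc_row[base], scores)


def sc_direct_fit(fc: ConnectivityMatrix, sc: ConnectivityMatrix,
                  min_connections: int = MIN_SAMPLES):
    """Per-region fit of FC weights on raw SC weights over that region's
    structural connections only (the region's connection 'mask').  Regions
    with too few connections return NaN."""
    n = fc.n_nodes
    r2 = np.full(n, np.nan)
    for i in range(n):
        mask = sc.values[i] > 0
        mask[i] = False
        if mask.sum() < min_connections:
            continue
        r2[i], _ = _r2_masked(fc.values[i, mask], sc.values[i, mask])
    return r2


def optimal_frequency(best_labels: np.ndarray, labels: list[str]) -> np.ndarray:
    """Per-region fraction of subjects for which each predictor was optimal.

    ``best_labels`` has shape (n_subjects, n_regions); rows of the output
    (region x predictor) sum to 1.
    """
    best_labels = np.asarray(best_labels, dtype=object)
    n_sub, n_reg = best_labels.shape
    idx = {lbl: k for k, lbl in enumerate(labels)}
    h = np.zeros((n_reg, len(labels)))
    for s in range(n_sub):
        for r in range(n_reg):
            h[r, idx[best_labels[s, r]]] += 1
    return h / n_sub


def predictor_embedding(regional_r2_mean: np.ndarray, k: int = 4):
    """Two-dimensional embedding of predictors by the similarity of their
    regional coupling maps.

    Correlates predictors' regional-R2 vectors, keeps each predictor's k
    largest neighbours, symmetrises by union, and takes the first two
    principal components of the thresholded matrix without centering or
    z-scoring.  Returns ``(coords (p x 2), thresholded similarity)``.
    """
    r2 = np.asarray(regional_r2_mean, dtype=float)
    p = r2.shape[1]
    if p < 5:
        raise ValueError("embedding needs at least 5 predictors")
    if np.any(r2.std(axis=0) <= 1e-12 * (np.abs(r2).max() + 1)):
        raise ValueError("constant regional-R2 vector: correlation undefined")
    sim = np.corrcoef(r2.T)
    np.fill_diagonal(sim, -np.inf)
    keep = np.zeros_like(sim, dtype=bool)
    order = np.argsort(-sim, axis=1)
    for i in range(p):
        keep[i, order[i, :k]] = True
    keep |= keep.T
    np.fill_diagonal(sim, 1.0)  # self-similarity retained in the thresholded matrix
    np.fill_diagonal(keep, True)
    thr = np.where(keep, sim, 0.0)
    u, s, _ = np.linalg.svd(thr)
    coords = u[:, :2] * s[:2]
    return coords, thr
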