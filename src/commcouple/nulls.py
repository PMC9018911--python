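"""Spatially constrained permutation (spin) nulls and related tests.

Parcellated brain maps are spatially autocorrelated, so naive shuffling
nulls overstate significance.  The spin test instead applies a uniformly
random 3D rotation to the parcels' positions on the sphere and re-assigns
each parcel the value of the nearest rotated parcel, preserving the map's
spatial covariance structure.  Assignment is greedy one-to-one in a random
parcel order so that every null map is an exact permutation of the
original values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import special_ortho_group
from statsmodels.stats.multitest import multipletests

from .graph_core import ConnectivityMatrix
from .regression import _r2_masked

__all__ = [
    "SpinPermutationSet",
    "spin_permutations",
    "greedy_assignment",
    "system_enrichment",
    "subject_significance",
    "bh_fdr",
    "floor_null",
]


@dataclass
class SpinPermutationSet:
    """Bank of spatial permutations; row r maps parcel i to the original
    parcel ``permutations[r, i]`` whose value it receives."""

    permutations: np.ndarray
    seed: int

    @property
    def n_perm(self) -> int:
        return self.permutations.shape[0]

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Spun copies of a parcel map, shape (n_perm, N)."""
        return np.asarray(values)[self.permutations]


def spin_permutations(sphere_coords: np.ndarray, n_perm: int = 1000,
                      seed: int = 0, method: str = "optimal") -> SpinPermutationSet:
    """Generate rotation-based spatial permutations of parcels.

    For each permutation a uniform random rotation is applied to the unit-
    sphere coordinates and parcels are matched one-to-one to rotated
    parcels, so every null map is an exact permutation of the original
    values.  ``method="optimal"`` solves the assignment problem exactly
    (minimum total displacement; best preservation of spatial structure),
    ``method="greedy"`` matches nearest-first in random parcel order.
    """
    coords = np.asarray(sphere_coords, dtype=float)
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    if np.any(d[~np.eye(n, dtype=bool)] < 1e-9):
        raise ValueError("duplicate sphere coordinates")
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.int64)
    for r in range(n_perm):
        rot = special_ortho_group.rvs(3, random_state=rng)
        rotated = coords @ rot.T
        if method == "greedy":
            perms[r] = greedy_assignment(coords, rotated, rng.permutation(n))
        else:
            dist = np.linalg.norm(coords[:, None] - rotated[None, :], axis=-1)
            perms[r] = linear_sum_assignment(dist)[1]
    return SpinPermutationSet(permutations=perms, seed=seed)


def greedy_assignment(coords: np.ndarray, rotated: np.ndarray,
                      order: np.ndarray) -> np.ndarray:
    """One-to-one nearest-neighbour matching of parcels to rotated parcels,
    processed in the given order; returns a permutation of 0..N-1."""
    n = coords.shape[0]
    dist = np.linalg.norm(coords[:, None] - rotated[None, :], axis=-1)
    taken = np.zeros(n, dtype=bool)
    perm = np.empty(n, dtype=np.int64)
    for i in order:
        j = int(np.argmin(np.where(taken, np.inf, dist[i])))
        perm[i] = j
        taken[j] = True
    return perm


def system_enrichment(values: np.ndarray, system_labels: np.ndarray,
                      spins: SpinPermutationSet, q: float = 0.05,
                      min_parcels: int = 3, alternative: str = "two-sided"):
    """System-mean enrichment against the spin null.

    Averages a parcel map within each system and compares each observed
    mean with the null distribution of system means over spun maps.  By
    default the p-value is two-sided around the null median (over- and
    under-representation both count); for directional hypotheses,
    ``alternative="less"`` (or ``"greater"``) tests only the stated tail.
    All p-values carry the +1 correction and Benjamini-Hochberg controls
    the FDR across systems at ``q``.

    Returns a dict with systems, observed means, p-values, the rejection
    mask, and the adjusted critical p-value (largest rejected p, NaN when
    nothing is rejected).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(system_labels)
    systems = np.unique(labels)
    ind = np.stack([(labels == s) / (labels == s).sum() for s in systems])
    for s, m in zip(systems, ind):
        if (m > 0).sum() < min_parcels:
            raise ValueError(f"system {s!r} has fewer than {min_parcels} parcels")
    obs = ind @ values
    null = spins.apply(values) @ ind.T  # (n_perm, n_systems)
    if alternative == "two-sided":
        med = np.median(null, axis=0)
        exceed = (np.abs(null - med) >= np.abs(obs - med)[None, :]).sum(axis=0)
    elif alternative == "less":
        exceed = (null <= obs[None, :]).sum(axis=0)
    elif alternative == "greater":
        exceed = (null >= obs[None, :]).sum(axis=0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + exceed) / (1.0 + spins.n_perm)
    crit, reject = bh_fdr(p, q)
    return {
        "systems": systems,
        "observed": obs,
        "null_mean": null.mean(axis=0),
        "p": p,
        "reject": reject,
        "p_crit": crit,
    }


def subject_significance(fc: ConnectivityMatrix, predictor: np.ndarray,
                         spins: SpinPermutationSet) -> float:
    """One-sided spin p-value for a global edge-wise R2.

    Null R2 values come from refitting after jointly permuting the rows and
    columns of the predictor matrix with each spin.
    """
    n = fc.n_nodes
    iu = np.triu_indices(n, 1)
    y = fc.values[iu]
    obs, _ = _r2_masked(y, predictor[iu])
    count = 0
    for perm in spins.permutations:
        spun = predictor[np.ix_(perm, perm)]
        r2, _ = _r2_masked(y, spun[iu])
        if np.isfinite(r2) and r2 >= obs:
            count += 1
    return (1.0 + count) / (1.0 + spins.n_perm)


def bh_fdr(pvals: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up; returns the adjusted critical value
    (largest rejected raw p, NaN if none) and the rejection mask."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    crit = float(p[reject].max()) if reject.any() else np.nan
    return crit, reject


def floor_null(fc_row: np.ndarray, predictor_row: np.ndarray,
               n_rep: int = 100, seed: int = 0, percentile: float = 95.0):
    """Permutation floor for one regional fit.

    The predictor row is shuffled ``n_rep`` times and refit; the floor is
    the 95th percentile of the null R2 distribution.  A region whose
    observed R2 does not exceed its floor is flagged 'at floor'.
    Returns ``(floor, observed r2, at_floor flag)``.
    """
    rng = np.random.default_rng(seed)
    obs, _ = _r2_masked(fc_row, predictor_row)
    null = np.empty(n_rep)
    for r in range(n_rep):
        null[r], _ = _r2_masked(fc_row, rng.permutation(predictor_row))
    floor = np.nanpercentile(null, percentile)
    return floor, obs, bool(obs <= floor)
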