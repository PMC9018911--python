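"""Shared graph containers, validation, and the weight-to-cost transform.

Structural connectivity (SC) is a sparse, weighted, undirected network of
anatomical links between brain regions; functional connectivity (FC) is a
dense matrix of inter-regional activity correlations.  Both are carried as
symmetric, zero-diagonal matrices.  Several path-based communication models
require converting edge affinities (weights) into traversal costs, which is
done here with the power-law map ``C_ij = A_ij ** -gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ConnectivityMatrix",
    "ParcelGeometry",
    "CostMatrix",
    "validate_connectivity",
    "weight_to_cost",
    "load_matrix",
    "save_matrix",
    "load_geometry",
]

#: gamma values used for the weighted path-based predictors in the battery
BATTERY_GAMMAS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0)

#: Markov times at which flow graphs are evaluated in the battery
BATTERY_MARKOV_TIMES = (1.0, 2.5, 5.0, 10.0)

_SYM_TOL = 1e-8


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative matrix with zero diagonal.

    ``kind`` distinguishes structural ("structural"), functional
    ("functional") and derived predictor ("predictor") matrices; structural
    matrices are additionally required to be connected.
    """

    values: np.ndarray
    kind: str = "structural"
    connected: bool | None = field(default=None)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class ParcelGeometry:
    """Per-parcel geometry: centroids (mm), unit-sphere coordinates used by
    the spin test, a system label and a hemisphere flag for each parcel."""

    centroids: np.ndarray
    sphere_coords: np.ndarray
    system_labels: np.ndarray
    hemisphere: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.sphere_coords = np.asarray(self.sphere_coords, dtype=float)
        self.system_labels = np.asarray(self.system_labels)
        if self.centroids.shape != self.sphere_coords.shape:
            raise ValueError("centroids and sphere_coords shapes differ")
        norms = np.linalg.norm(self.sphere_coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("sphere_coords rows must have unit norm")
        if self.hemisphere is None:
            self.hemisphere = (self.centroids[:, 0] > 0).astype(int)

    @property
    def n_parcels(self) -> int:
        return self.centroids.shape[0]

    @property
    def systems(self) -> np.ndarray:
        return np.unique(self.system_labels)


@dataclass
class CostMatrix:
    """Traversal costs derived from weights; +inf marks absent edges."""

    values: np.ndarray
    gamma: float

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def validate_connectivity(matrix, kind: str = "structural") -> ConnectivityMatrix:
    """Validate and canonicalise a square connectivity matrix.

    Small asymmetries (up to 1e-8, e.g. from file round-trips) are averaged
    out; larger ones are rejected.  The diagonal is zeroed.  Structural
    matrices must be nonnegative and form a single connected component.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("connectivity matrix contains non-finite entries")
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > _SYM_TOL:
        raise ValueError(f"matrix asymmetry {asym:.3g} exceeds tolerance {_SYM_TOL}")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    connected = None
    if kind == "structural":
        if np.any(m < 0):
            raise ValueError("structural weights must be nonnegative")
        n_comp, _ = connected_components(m > 0, directed=False)
        connected = n_comp == 1
        if not connected:
            raise ValueError(f"structural graph is disconnected ({n_comp} components)")
    return ConnectivityMatrix(values=m, kind=kind, connected=connected)


def weight_to_cost(sc: ConnectivityMatrix, gamma: float) -> CostMatrix:
    """Map affinities to costs via ``C_ij = A_ij ** -gamma``.

    Stronger connections become cheaper to traverse; absent edges get
    infinite cost so shortest-path routines treat them uniformly.  The
    diagonal stays zero.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    a = sc.values
    with np.errstate(divide="ignore"):
        c = np.where(a > 0, np.power(np.where(a > 0, a, 1.0), -gamma), np.inf)
    np.fill_diagonal(c, 0.0)
    return CostMatrix(values=c, gamma=gamma)


# --- delimited-text IO -----------------------------------------------------

def load_matrix(path, kind: str = "structural") -> ConnectivityMatrix:
    """Read an N x N matrix from delimited text (tab or comma, no header)."""
    m = np.loadtxt(path, delimiter=_sniff_delimiter(path))
    return validate_connectivity(m, kind=kind)


def save_matrix(matrix, path) -> None:
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix)
    np.savetxt(path, values, delimiter="\t", fmt="%.10g")


def load_geometry(centroid_path, sphere_path=None, labels_path=None) -> ParcelGeometry:
    """Read parcel geometry from delimited text files.

    ``centroid_path`` holds x,y,z in mm; ``sphere_path`` unit-sphere
    coordinates (defaults to normalised centroids); ``labels_path`` one
    system label per line.
    """
    cent = np.loadtxt(centroid_path, delimiter=_sniff_delimiter(centroid_path))
    if sphere_path is not None:
        sph = np.loadtxt(sphere_path, delimiter=_sniff_delimiter(sphere_path))
    else:
        sph = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    if labels_path is not None:
        with open(labels_path) as fh:
            labels = np.array([line.strip() for line in fh if line.strip()])
    else:
        labels = np.array(["all"] * cent.shape[0])
    return ParcelGeometry(centroids=cent, sphere_coords=sph, system_labels=labels)


def _sniff_delimiter(path) -> str | None:
    with open(path) as fh:
        first = fh.readline()
    if "," in first and "\t" not in first:
        return ","
    return None  # any whitespace
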