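"""The communication-model predictor battery.

Each predictor transforms one sparse structural connectivity (SC) matrix
(plus parcel geometry) into a fully weighted N x N matrix encoding a
stylised signalling process: diffusion (flow graphs, communicability, mean
first passage time), routing (shortest path length, navigation, search
information, path transitivity), topological similarity (matching index,
cosine similarity), or pure geometry (Euclidean distance).

The full battery holds 40 predictors across these ten classes: binary and
weighted flow graphs at four Markov times (8), navigation hop count and
metric length (2), binary and weighted communicability (2), path
transitivity for the binary graph and six weight-to-cost exponents (7),
matching index (2), shortest path length (7), cosine similarity (2), search
information (7), mean first passage time (2) and Euclidean distance (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _dijkstra

from .graph_core import (
    BATTERY_GAMMAS,
    BATTERY_MARKOV_TIMES,
    ConnectivityMatrix,
    CostMatrix,
    ParcelGeometry,
    weight_to_cost,
)

__all__ = [
    "PredictorStack",
    "flow_graph",
    "navigation",
    "communicability",
    "matching_index",
    "shortest_path_length",
    "shortest_paths",
    "path_transitivity",
    "cosine_similarity",
    "search_information",
    "mean_first_passage_time",
    "euclidean_matrix",
    "hop_distance",
    "build_battery",
]

PREDICTOR_CLASSES = (
    "flow graph",
    "navigation",
    "communicability",
    "path transitivity",
    "matching index",
    "path length",
    "cosine similarity",
    "search information",
    "mean first passage time",
    "euclidean",
)


@dataclass
class PredictorStack:
    """Ordered, labelled collection of predictor matrices for one subject."""

    matrices: list[np.ndarray]
    labels: list[str]
    class_of: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.matrices[self.labels.index(label)]

    @property
    def n_classes(self) -> int:
        return len(set(self.class_of.values()))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lbl in self.labels:
            cls = self.class_of[lbl]
            counts[cls] = counts.get(cls, 0) + 1
        return counts

    def as_array(self) -> np.ndarray:
        return np.stack(self.matrices)


def _binarize(a: np.ndarray) -> np.ndarray:
    return (a > 0).astype(float)


def _strength(a: np.ndarray) -> np.ndarray:
    return a.sum(axis=1)


def _symmetrize(m: np.ndarray) -> np.ndarray:
    out = (m + m.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


# --- flow graphs -----------------------------------------------------------

def flow_graph(sc: ConnectivityMatrix, t: float, variant: str = "weighted") -> np.ndarray:
    """Flow graph: Markov-process dynamics embedded into edge weights.

    For a continuous-time random walk with random-walk Laplacian
    ``L = I - A D^-1`` the flow graph at Markov time ``t`` is
    ``A'(t) = expm(-t L) @ D`` with ``D = diag(s)``, ``s_i = sum_j A_ij``.
    The result is symmetric and conserves each node's strength as a column
    marginal: ``sum_i A'(t)_ij = s_j``.
    """
    a = _binarize(sc.values) if variant == "binary" else sc.values
    s = _strength(a)
    if np.any(s == 0):
        raise ValueError("flow graph undefined for isolated nodes (zero strength)")
    lap = np.eye(len(s)) - a / s[None, :]  # I - A D^-1
    return expm(-t * lap) * s[None, :]


# --- navigation ------------------------------------------------------------

def navigation(sc: ConnectivityMatrix, geometry: ParcelGeometry):
    """Greedy geometric routing: always hop to the neighbour nearest the
    target in Euclidean space.

    Returns ``(nav_num, nav_ms)``: hop counts and summed Euclidean edge
    lengths of the realised paths.  A walk that fails to reach its target
    within N hops has entered a cycle; both outputs carry +inf for such
    pairs.  Outputs are symmetrised by the element-wise mean of the two
    directions, with inf dominating.
    """
    a = sc.values
    adj = a > 0
    n = a.shape[0]
    euc = euclidean_matrix(geometry)
    num = np.zeros((n, n))
    ms = np.zeros((n, n))
    nodes = np.arange(n)
    for t in range(n):
        # successor of i en route to t: adjacent j minimising euc[j, t];
        # argmin ties resolve to the lowest index
        cand = np.where(adj, euc[:, t][None, :], np.inf)
        succ = np.argmin(cand, axis=1)
        cur = nodes.copy()
        hops = np.zeros(n)
        length = np.zeros(n)
        for _ in range(n):
            active = cur != t
            if not active.any():
                break
            nxt = succ[cur]
            step = euc[cur, nxt]
            hops[active] += 1
            length[active] += step[active]
            cur = np.where(active, nxt, cur)
        failed = cur != t
        hops[failed] = np.inf
        length[failed] = np.inf
        num[:, t] = hops
        ms[:, t] = length
    return _symmetrize(num), _symmetrize(ms)


# --- communicability -------------------------------------------------------

def communicability(sc: ConnectivityMatrix, variant: str = "weighted") -> np.ndarray:
    """Weighted sum of walks of all lengths: ``G = expm(A)`` for the binary
    graph, ``G = expm(D^-1/2 A D^-1/2)`` for the weighted graph."""
    if variant == "binary":
        return expm(_binarize(sc.values))
    a = sc.values
    s = _strength(a)
    if np.any(s == 0):
        raise ValueError("weighted communicability undefined for isolated nodes")
    d = 1.0 / np.sqrt(s)
    return expm(d[:, None] * a * d[None, :])


# --- matching index --------------------------------------------------------

def matching_index(sc: ConnectivityMatrix, variant: str = "binary") -> np.ndarray:
    """Normalised overlap of two nodes' connection profiles, excluding the
    pair itself.

    Binary: ``|G_i\\j intersect G_j\\i| / |G_i\\j union G_j\\i|``.  The
    weighted variant uses the weighted Jaccard ratio
    ``sum_k min(A_ik, A_jk) / sum_k max(A_ik, A_jk)`` over k != i, j, which
    reduces exactly to the binary formula when all weights are 1.
    """
    a = _binarize(sc.values) if variant == "binary" else sc.values
    n = a.shape[0]
    m = np.zeros((n, n))
    diag = np.arange(n)
    for i in range(n):
        ai = a[i]
        mins = np.minimum(ai[None, :], a)  # row j holds min(A_ik, A_jk) over k
        maxs = np.maximum(ai[None, :], a)
        # exclude k == i and k == j; min-terms there vanish (zero diagonal)
        num = mins.sum(axis=1) - mins[:, i] - mins[diag, diag]
        den = maxs.sum(axis=1) - maxs[:, i] - maxs[diag, diag]
        with np.errstate(invalid="ignore", divide="ignore"):
            m[i] = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(m, 0.0)
    return m


# --- shortest paths --------------------------------------------------------

def _cost_values(sc: ConnectivityMatrix, gamma_or_binary) -> np.ndarray:
    if gamma_or_binary == "binary" or gamma_or_binary is None:
        c = np.where(sc.values > 0, 1.0, np.inf)
        np.fill_diagonal(c, 0.0)
        return c
    if isinstance(gamma_or_binary, CostMatrix):
        return gamma_or_binary.values
    return weight_to_cost(sc, float(gamma_or_binary)).values


def shortest_paths(cost: np.ndarray):
    """All-pairs shortest-path distances and a canonical predecessor table.

    Distances come from Dijkstra on the finite-cost edges.  Path degeneracy
    is resolved deterministically: the predecessor of ``t`` on the canonical
    path from ``s`` is the lowest-index node ``j`` with
    ``d(s, j) + C(j, t) == d(s, t)``.
    """
    n = cost.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(cost) & off
    rows, cols = np.nonzero(finite)
    graph = csr_matrix((cost[rows, cols], (rows, cols)), shape=(n, n))
    dist = _dijkstra(graph, directed=False)
    pred = np.full((n, n), -1, dtype=np.int64)
    c = np.where(finite, cost, np.inf)
    for s in range(n):
        d = dist[s]
        # candidate predecessors j of each target t
        tot = d[:, None] + c  # tot[j, t]
        ok = np.abs(tot - d[None, :]) <= 1e-9 * (1.0 + np.abs(d[None, :]))
        np.fill_diagonal(ok, False)
        has = ok.any(axis=0)
        pred[s, has] = np.argmax(ok[:, has], axis=0)
        pred[s, s] = s
    return dist, pred


def reconstruct_path(pred: np.ndarray, s: int, t: int) -> list[int]:
    """Node sequence of the canonical shortest path from s to t."""
    path = [t]
    cur = t
    while cur != s:
        cur = int(pred[s, cur])
        path.append(cur)
    path.reverse()
    return path


def shortest_path_length(sc: ConnectivityMatrix, gamma_or_binary="binary") -> np.ndarray:
    """All-pairs minimal traversal cost (hop count for the binary graph)."""
    dist, _ = shortest_paths(_cost_values(sc, gamma_or_binary))
    np.fill_diagonal(dist, 0.0)
    return dist


def hop_distance(sc: ConnectivityMatrix) -> np.ndarray:
    """Binary shortest-path hop counts (used to stratify edge-wise fits)."""
    return shortest_path_length(sc, "binary")


# --- path transitivity -----------------------------------------------------

def path_transitivity(sc: ConnectivityMatrix, gamma_or_binary="binary",
                      paths: tuple | None = None) -> np.ndarray:
    """Mean matching index over all node pairs on the shortest path.

    For the canonical shortest path ``pi(s, t)`` with ``k >= 2`` nodes,
    ``PT_st = 2 / (k (k - 1)) * sum_{i < j in pi} M_ij`` where M is the
    matching index of the corresponding variant (binary matching with binary
    paths; weighted matching with each weight-to-cost exponent).  A direct
    edge (k = 2) gives ``PT_st = M_st``.
    """
    variant = "binary" if gamma_or_binary == "binary" else "weighted"
    m = matching_index(sc, variant)
    if paths is None:
        paths = shortest_paths(_cost_values(sc, gamma_or_binary))
    _, pred = paths
    n = sc.n_nodes
    pt = np.zeros((n, n))
    for s in range(n):
        for t in range(s + 1, n):
            nodes = reconstruct_path(pred, s, t)
            k = len(nodes)
            sub = m[np.ix_(nodes, nodes)]
            pt[s, t] = pt[t, s] = sub[np.triu_indices(k, 1)].sum() * 2.0 / (k * (k - 1))
    return pt


# --- cosine similarity -----------------------------------------------------

def cosine_similarity(sc: ConnectivityMatrix, variant: str = "weighted") -> np.ndarray:
    """Cosine of the angle between two regions' connection profiles after
    deleting entries i and j from both rows; zero-norm profiles give 0."""
    a = _binarize(sc.values) if variant == "binary" else sc.values
    dot = a @ a  # entries i, j of both rows are zero-diagonal products
    sq = (a ** 2).sum(axis=1)
    ni = sq[:, None] - a ** 2  # ||row i|| with entry j removed (entry i is 0)
    nj = sq[None, :] - a ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where((ni > 0) & (nj > 0), dot / np.sqrt(ni * nj), 0.0)
    np.fill_diagonal(s, 0.0)
    return s


# --- search information ----------------------------------------------------

def search_information(sc: ConnectivityMatrix, gamma_or_binary="binary",
                       paths: tuple | None = None) -> np.ndarray:
    """Bits needed for a random walker to follow the shortest path.

    The probability of the canonical path is the product of single-step
    transition probabilities ``p_ij = A_ij / s_i`` (binary weights for the
    binary variant, raw weights otherwise); the information is
    ``SI = -log2 P``, which is nonnegative.  Output symmetrised by the mean
    of the two directions.
    """
    a = _binarize(sc.values) if gamma_or_binary == "binary" else sc.values
    s = _strength(a)
    p = a / s[:, None]
    logp = np.where(a > 0, np.log2(np.where(p > 0, p, 1.0)), -np.inf)
    if paths is None:
        paths = shortest_paths(_cost_values(sc, gamma_or_binary))
    _, pred = paths
    n = sc.n_nodes
    si = np.zeros((n, n))
    for src in range(n):
        for t in range(n):
            if src == t:
                continue
            nodes = reconstruct_path(pred, src, t)
            si[src, t] = -sum(logp[nodes[k], nodes[k + 1]] for k in range(len(nodes) - 1))
    return _symmetrize(si)


# --- mean first passage time ----------------------------------------------

def mean_first_passage_time(sc: ConnectivityMatrix, variant: str = "weighted",
                            z_score: bool = True) -> np.ndarray:
    """Expected number of discrete random-walk steps from node i to node j.

    Computed from the fundamental matrix ``Z = inv(I - P + 1 pi^T)`` with
    ``P = D^-1 A`` and stationary distribution ``pi_j = s_j / sum(s)``:
    ``MFPT_ij = (Z_jj - Z_ij) / pi_j``.  Columns are then z-scored over
    their off-diagonal entries to remove nodal biases, and the matrix is
    symmetrised by the element-wise mean.
    """
    a = _binarize(sc.values) if variant == "binary" else sc.values
    s = _strength(a)
    if np.any(s == 0):
        raise ValueError("MFPT undefined for isolated nodes")
    n = a.shape[0]
    p = a / s[:, None]
    pi = s / s.sum()
    z = np.linalg.inv(np.eye(n) - p + np.outer(np.ones(n), pi))
    mfpt = (np.diag(z)[None, :] - z) / pi[None, :]
    np.fill_diagonal(mfpt, 0.0)
    if not z_score:
        return mfpt
    out = np.empty_like(mfpt)
    off = ~np.eye(n, dtype=bool)
    for j in range(n):
        col = mfpt[off[:, j], j]
        out[:, j] = (mfpt[:, j] - col.mean()) / col.std(ddof=1)
    np.fill_diagonal(out, 0.0)
    return _symmetrize(out)


# --- Euclidean distance ----------------------------------------------------

def euclidean_matrix(geometry: ParcelGeometry) -> np.ndarray:
    """Pairwise Euclidean distance between regional centroids."""
    c = geometry.centroids
    diff = c[:, None, :] - c[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


# --- the battery -----------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:g}"


def build_battery(sc: ConnectivityMatrix, geometry: ParcelGeometry,
                  gammas=BATTERY_GAMMAS, markov_times=BATTERY_MARKOV_TIMES) -> PredictorStack:
    """Compute the full 40-predictor battery for one subject.

    Shortest-path computations are shared between the path-length, search-
    information and path-transitivity families at each weight-to-cost
    exponent.  All outputs are symmetric with zero diagonal; only the two
    navigation matrices may contain +inf (failed greedy routes).
    """
    matrices: list[np.ndarray] = []
    labels: list[str] = []
    class_of: dict[str, str] = {}

    def add(label: str, cls: str, mat: np.ndarray) -> None:
        matrices.append(mat)
        labels.append(label)
        class_of[label] = cls

    for variant in ("bin", "wei"):
        v = "binary" if variant == "bin" else "weighted"
        for t in markov_times:
            add(f"fg-{variant}-{_fmt(t)}", "flow graph", _symmetrize(flow_graph(sc, t, v)))

    nav_num, nav_ms = navigation(sc, geometry)
    add("nav-num", "navigation", nav_num)
    add("nav-ms", "navigation", nav_ms)

    add("comm-bin", "communicability", _symmetrize(communicability(sc, "binary")))
    add("comm-wei", "communicability", _symmetrize(communicability(sc, "weighted")))

    # shared shortest-path machinery
    bin_paths = shortest_paths(_cost_values(sc, "binary"))
    gamma_paths = {g: shortest_paths(_cost_values(sc, g)) for g in gammas}

    add("pt-bin", "path transitivity", path_transitivity(sc, "binary", paths=bin_paths))
    for g in gammas:
        add(f"pt-wei-{_fmt(g)}", "path transitivity",
            path_transitivity(sc, g, paths=gamma_paths[g]))

    add("mi-bin", "matching index", matching_index(sc, "binary"))
    add("mi-wei", "matching index", matching_index(sc, "weighted"))

    pl_bin = bin_paths[0].copy()
    np.fill_diagonal(pl_bin, 0.0)
    add("pl-bin", "path length", pl_bin)
    for g in gammas:
        pl = gamma_paths[g][0].copy()
        np.fill_diagonal(pl, 0.0)
        add(f"pl-wei-{_fmt(g)}", "path length", pl)

    add("cos-bin", "cosine similarity", cosine_similarity(sc, "binary"))
    add("cos-wei", "cosine similarity", cosine_similarity(sc, "weighted"))

    add("si-bin", "search information", search_information(sc, "binary", paths=bin_paths))
    for g in gammas:
        add(f"si-wei-{_fmt(g)}", "search information",
            search_information(sc, g, paths=gamma_paths[g]))

    add("mfpt-bin", "mean first passage time", mean_first_passage_time(sc, "binary"))
    add("mfpt-wei", "mean first passage time", mean_first_passage_time(sc, "weighted"))

    add("euc", "euclidean", euclidean_matrix(geometry))

    return PredictorStack(matrices=matrices, labels=labels, class_of=class_of)
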