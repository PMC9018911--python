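"""Consensus clustering of regions by their optimal-predictor preferences.

Regions are compared through the Pearson correlation of their
optimal-predictor frequency vectors (which predictor wins for how many
subjects), giving a signed similarity matrix S.  Communities maximise the
modularity Q = sum_ij B_ij delta(sigma_i, sigma_j) with a uniform null,
B_ij = S_ij - gamma, using a generalised Louvain procedure; by default the
resolution gamma equals the mean off-diagonal similarity.  Louvain is
stochastic, so a consensus loop re-clusters the co-assignment probability
matrix (minus its analytic chance expectation) until every run agrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Partition",
    "preference_similarity",
    "modularity_louvain",
    "consensus_partition",
]


@dataclass
class Partition:
    """Community labels (contiguous integers from 1) with the resolution
    and modularity value at which they were found."""

    labels: np.ndarray
    gamma: float
    q: float

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))


def preference_similarity(h: np.ndarray) -> np.ndarray:
    """Region-by-region Pearson correlation of optimal-predictor frequency
    vectors; diagonal zeroed."""
    h = np.asarray(h, dtype=float)
    if np.any(h.std(axis=1) == 0):
        raise ValueError("zero-variance preference row: correlation undefined")
    s = np.corrcoef(h)
    np.fill_diagonal(s, 0.0)
    return s


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out + 1


def _modularity(b: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return float(b[same].sum())


def _louvain_on_b(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Generalised Louvain on a signed modularity matrix: local moving in
    random node order, then aggregation, until no further gain.

    The move gain for node i joining community c is
    ``2 * sum_{j in c, j != i} B_ij`` (signed B evaluated as printed, no
    separate positive/negative weighting); moving to a fresh singleton
    community has gain ``-2 * sum_{j in own} B_ij`` and is taken when every
    attachment is unfavourable.
    """
    n = b.shape[0]
    node_to_comm = np.arange(n)
    b_cur = b.copy()
    np.fill_diagonal(b_cur, 0.0)
    while True:
        m = b_cur.shape[0]
        comm = np.arange(m)
        moved_any = False
        improved = True
        while improved:
            improved = False
            for i in rng.permutation(m):
                sums = np.zeros(comm.max() + 2)
                np.add.at(sums, comm, b_cur[i])  # b_cur[i, i] = 0
                # last slot is an always-empty community (isolation move)
                best = int(np.argmax(sums))
                if sums[best] > sums[comm[i]] + 1e-12 and best != comm[i]:
                    comm[i] = best
                    improved = True
                    moved_any = True
        uniq, inv = np.unique(comm, return_inverse=True)
        node_to_comm = inv[node_to_comm]
        if not moved_any or len(uniq) == m:
            break
        ind = np.zeros((m, len(uniq)))
        ind[np.arange(m), inv] = 1.0
        b_cur = ind.T @ b_cur @ ind
        np.fill_diagonal(b_cur, 0.0)
    return _relabel(node_to_comm)


def modularity_louvain(s: np.ndarray, gamma: float | None = None,
                       seed: int = 0) -> Partition:
    """Single Louvain run on B = S - gamma (uniform null P_ij = 1).

    ``gamma=None`` uses the mean off-diagonal similarity.  Node order is
    randomised per seed.
    """
    s = np.asarray(s, dtype=float)
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    n = s.shape[0]
    off = ~np.eye(n, dtype=bool)
    if gamma is None:
        gamma = float(s[off].mean())
    b = s - gamma
    np.fill_diagonal(b, 0.0)
    rng = np.random.default_rng(seed)
    labels = _louvain_on_b(b, rng)
    return Partition(labels=labels, gamma=gamma, q=_modularity(b, labels))


def consensus_partition(s: np.ndarray, gamma: float | None = None,
                        n_runs: int = 1000, seed: int = 0,
                        max_iter: int = 50) -> Partition:
    """Iterative consensus over stochastic Louvain runs.

    Each round runs Louvain ``n_runs`` times, forms the co-assignment
    probability matrix, subtracts the chance co-assignment expected from
    each run's community sizes (sum_c n_c (n_c - 1) / (N (N - 1)), averaged
    over runs), and re-clusters the difference.  Terminates when all runs
    return the same partition.
    """
    s = np.asarray(s, dtype=float)
    n = s.shape[0]
    rng = np.random.default_rng(seed)
    off = ~np.eye(n, dtype=bool)
    if gamma is None:
        gamma = float(s[off].mean())
    b = s - gamma
    np.fill_diagonal(b, 0.0)
    mat = b
    for _ in range(max_iter):
        runs = []
        for _ in range(n_runs):
            sub = np.random.default_rng(rng.integers(2 ** 31 - 1))
            runs.append(_louvain_on_b(mat, sub))
        first = runs[0]
        if all(np.array_equal(_agree_canon(r), _agree_canon(first)) for r in runs[1:]):
            q = _modularity(b, first)
            return Partition(labels=_relabel(first), gamma=gamma, q=q)
        co = np.zeros((n, n))
        expected = 0.0
        for r in runs:
            co += (r[:, None] == r[None, :]).astype(float)
            _, counts = np.unique(r, return_counts=True)
            expected += (counts * (counts - 1)).sum() / (n * (n - 1))
        co /= n_runs
        expected /= n_runs
        mat = co - expected
        np.fill_diagonal(mat, 0.0)
    raise RuntimeError(f"consensus did not converge in {max_iter} iterations")


def _agree_canon(labels: np.ndarray) -> np.ndarray:
    """Canonical form invariant to label permutation (first-occurrence order)."""
    seen: dict[int, int] = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lbl in enumerate(labels):
        out[i] = seen.setdefault(int(lbl), len(seen))
    return out
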