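"""Exact k-nearest-neighbor similarity graph.

Both restoration algorithms share this substrate: for every document i, the
k most cosine-similar other documents K(i), with edge weight
w_ij = sim(x_i, x_j) for j in K(i) and 0 otherwise.  Edges are directed
(j in K(i) does not imply i in K(j)); similarity itself is symmetric.
Ties in similarity break by ascending document index so graphs are
bit-reproducible across runs and platforms.  Search is exact brute force —
n here is thousands at most.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


def cosine_sim(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity; 0 by convention if either vector is zero."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(x @ y / (nx * ny))


@dataclass(frozen=True)
class NeighborGraph:
    """k-NN graph: per-row neighbor ids (descending similarity) and weights."""

    k: int
    indices: np.ndarray  # (n, k) neighbor ids per node
    weights: np.ndarray  # (n, k) cosine similarities

    @property
    def n_nodes(self) -> int:
        return self.indices.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[i]

    def to_sparse(self) -> sp.csr_matrix:
        """Directed adjacency W with W[i, j] = w_ij for j in K(i)."""
        n, k = self.indices.shape
        rows = np.repeat(np.arange(n), k)
        return sp.csr_matrix(
            (self.weights.ravel(), (rows, self.indices.ravel())), shape=(n, n)
        )

    def symmetrized(self) -> sp.csr_matrix:
        """max(W, W.T) — an undirected view; off by default everywhere."""
        W = self.to_sparse()
        return W.maximum(W.T)

    def save_edges_tsv(self, path) -> None:
        n, k = self.indices.shape
        with open(path, "w") as fh:
            fh.write("source\tneighbor\tweight\n")
            for i in range(n):
                for j, w in zip(self.indices[i], self.weights[i]):
                    fh.write(f"{i}\t{j}\t{w:.17g}\n")


def _block_similarity(X: sp.csr_matrix, block: slice) -> np.ndarray:
    return np.asarray((X[block] @ X.T).todense())


def build_graph(X: sp.spmatrix, k: int, block_size: int = 512) -> NeighborGraph:
    """Build the exact k-NN cosine graph over the rows of X.

    Rows are normalized internally if needed; zero rows have similarity 0
    to everything.  ``k >= n`` is clamped to ``n - 1`` with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = sp.csr_matrix(X, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 documents to build a neighbor graph")
    if k >= n:
        warnings.warn(f"k={k} >= n_docs={n}; clamped to {n - 1}")
        k = n - 1

    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    scale = np.where(norms == 0, 1.0, norms)
    Xn = sp.diags(1.0 / scale) @ X

    indices = np.empty((n, k), dtype=np.int64)
    weights = np.empty((n, k), dtype=np.float64)
    col_ids = np.arange(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        S = _block_similarity(sp.csr_matrix(Xn), slice(start, stop))
        for r, i in enumerate(range(start, stop)):
            row = S[r]
            row[i] = -np.inf  # no self-edges
            order = np.lexsort((col_ids, -row))[:k]
            indices[i] = order
            weights[i] = row[order]
    return NeighborGraph(k=k, indices=indices, weights=weights)
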