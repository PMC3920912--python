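"""Weighted k-nearest-neighbor restoration of missing labels.

For every (document, label) combination the score is the weight-normalized
vote of the document's k nearest training neighbors:

    S(d, cl) = sum_{d' in kNN(d)} w(d, d') * I(d' in cl)
               / sum_{d' in kNN(d)} w(d, d')

Every unlabeled pair with S >= T is proposed as a missing label.  The vote
weight w defaults to cosine similarity (closer neighbor, larger vote);
``weight='inverse-distance'`` uses 1/(1 - cos) instead, the alternative
reading of a distance-valued weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import NeighborGraph, build_graph
from .modification import RelevancePairs

_WEIGHT_MODES = ("similarity", "inverse-distance")
_INV_EPS = 1e-8


@dataclass(frozen=True)
class WkNNParams:
    """Neighbor count k and acceptance threshold T in [0, 1]."""

    k: int = 10
    T: float = 0.3
    weight: str = "similarity"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.T <= 1.0:
            raise ValueError("T must be in [0, 1]")
        if self.weight not in _WEIGHT_MODES:
            raise ValueError(f"weight must be one of {_WEIGHT_MODES}")


def _vote_weights(graph: NeighborGraph, mode: str) -> np.ndarray:
    if mode == "similarity":
        return np.maximum(graph.weights, 0.0)
    return 1.0 / (1.0 - np.minimum(graph.weights, 1.0) + _INV_EPS)


def wknn_score(
    d: int,
    cl: int,
    graph: NeighborGraph,
    Y: sp.spmatrix,
    weight: str = "similarity",
) -> float:
    """Score one (document, label) pair; in [0, 1].

    0 (with a warning) when every neighbor weight is zero.
    """
    Y = sp.csr_matrix(Y)
    w = _vote_weights(graph, weight)[d]
    total = w.sum()
    if total <= 0.0:
        warnings.warn(f"document {d}: all neighbor weights are zero; score := 0")
        return 0.0
    member = np.asarray(Y[graph.indices[d], cl].todense()).ravel()
    return float((w * member).sum() / total)


def wknn_score_table(
    graph: NeighborGraph, Y: sp.spmatrix, weight: str = "similarity"
) -> np.ndarray:
    """Dense n x m table of S(d, cl) for all combinations."""
    Y = sp.csr_matrix(Y, dtype=np.float64)
    w = _vote_weights(graph, weight)
    n, k = graph.indices.shape
    rows = np.repeat(np.arange(n), k)
    W = sp.csr_matrix((w.ravel(), (rows, graph.indices.ravel())), shape=(n, n))
    totals = np.asarray(W.sum(axis=1)).ravel()
    zero = totals <= 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} document(s) have all-zero neighbor weights; "
            "their scores := 0"
        )
    totals[zero] = 1.0
    S = np.asarray((W @ Y).todense()) / totals[:, None]
    S[zero] = 0.0
    return S


def restore_wknn(
    X: sp.spmatrix,
    Y: sp.spmatrix,
    params: WkNNParams,
    graph: NeighborGraph | None = None,
) -> RelevancePairs:
    """Propose missing pairs: {(d, cl): S(d, cl) >= T and Y[d, cl] = 0}.

    Already-positive pairs are never re-proposed.  A prebuilt graph may be
    passed to amortize neighbor search across thresholds.
    """
    Y = sp.csr_matrix(Y, dtype=np.int8)
    if graph is None:
        graph = build_graph(X, params.k)
    elif graph.k != min(params.k, graph.n_nodes - 1):
        raise ValueError(f"prebuilt graph has k={graph.k}, params ask k={params.k}")
    S = wknn_score_table(graph, Y, params.weight)
    unlabeled = np.asarray(Y.todense()) == 0
    hit = (S >= params.T) & unlabeled
    ds, cls_ = np.nonzero(hit)
    pairs = {(int(d), int(l)) for d, l in zip(ds, cls_)}
    scores = {(int(d), int(l)): float(S[d, l]) for d, l in zip(ds, cls_)}
    return RelevancePairs(pairs=pairs, scores=scores)
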