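"""Soft supervised learning (SoftSL) restoration of missing labels.

Each document i carries a class-membership distribution p_i over the m
labels; annotator assignments define reference distributions r_i (uniform
over the document's assigned labels).  Restoration minimizes the
misalignment functional over the k-NN similarity graph

    C1(p) = sum_{i labeled} KL(r_i || p_i)
          + mu * sum_i sum_{j in K(i)} w_ij KL(p_i || p_j)
          - nu * sum_i H(p_i)

where KL is the Kullback-Leibler divergence and H the Shannon entropy
(natural log).  The first term anchors p to the annotations, the second
makes graph-adjacent documents agree, the third (off by default: every
training document here carries at least one label) pushes toward uniform
distributions.  After minimization, every unlabeled (i, j) with
p_i^j >= T is proposed as a missing label.

The minimizer is an alternating scheme of exponentiated-gradient (mirror
descent) steps with backtracking on the step size, so the objective trace
is monotone non-increasing by construction and every iterate remains
row-stochastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import NeighborGraph, build_graph
from .modification import RelevancePairs


@dataclass(frozen=True)
class SoftSLParams:
    """SoftSL hyperparameters.

    k       neighbor count of the similarity graph;
    mu      weight of the graph-agreement term (>= 0);
    nu      weight of the entropy term (>= 0; default 0);
    T       category-assignment threshold on p_i^j (default 0.005);
    tol     relative objective-decrease tolerance for convergence;
    max_iter  iteration cap;
    eps     probability floor used when evaluating logs.
    """

    k: int = 10
    mu: float = 0.5
    nu: float = 0.0
    T: float = 0.005
    tol: float = 1e-6
    max_iter: int = 200
    eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mu < 0 or self.nu < 0:
            raise ValueError("mu and nu must be >= 0")
        if not 0.0 <= self.T <= 1.0:
            raise ValueError("T must be in [0, 1]")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.eps < 1e-2:
            raise ValueError("eps must be a small positive floor")


@dataclass
class ProbabilityTable:
    """Row-stochastic membership probabilities p and references r.

    ``labeled`` marks rows with annotator assignments (r_i defined there);
    unlabeled rows have uniform r by convention and no anchoring term.
    """

    p: np.ndarray
    r: np.ndarray
    labeled: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        self.r = np.asarray(self.r, dtype=np.float64)
        self.labeled = np.asarray(self.labeled, dtype=bool)
        if self.p.shape != self.r.shape:
            raise ValueError("p and r must have identical shapes")
        if self.labeled.shape != (self.p.shape[0],):
            raise ValueError("labeled must be a per-row boolean vector")
        for name, arr in (("p", self.p), ("r", self.r)):
            if (arr < 0).any():
                raise ValueError(f"{name} has negative entries")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError(f"rows of {name} must sum to 1")

    @classmethod
    def from_labels(cls, Y: sp.spmatrix) -> "ProbabilityTable":
        """r_i uniform over doc i's assigned labels; p0 = r (uniform if none)."""
        Yd = np.asarray(sp.csr_matrix(Y).todense(), dtype=np.float64)
        n, m = Yd.shape
        row_pos = Yd.sum(axis=1)
        labeled = row_pos > 0
        r = np.full((n, m), 1.0 / m)
        r[labeled] = Yd[labeled] / row_pos[labeled, None]
        return cls(p=r.copy(), r=r, labeled=labeled)


@dataclass
class SoftSLResult:
    """Minimization outcome: final table, objective trace, convergence flag."""

    table: ProbabilityTable
    trace: np.ndarray
    converged: bool
    n_iter: int = field(default=0)


def kl_divergence(p: np.ndarray, q: np.ndarray, eps: float = 1e-10) -> float:
    """KL(p || q) with both distributions floored at eps; >= 0."""
    p = np.clip(np.asarray(p, dtype=np.float64), eps, None)
    q = np.clip(np.asarray(q, dtype=np.float64), eps, None)
    return float(np.sum(p * (np.log(p) - np.log(q))))


def entropy(p: np.ndarray, eps: float = 1e-10) -> float:
    """Shannon entropy -sum p log p (nats), in [0, log m]."""
    p = np.clip(np.asarray(p, dtype=np.float64), eps, None)
    return float(-np.sum(p * np.log(p)))


def _objective_arrays(
    P: np.ndarray,
    R: np.ndarray,
    labeled: np.ndarray,
    W: sp.csr_matrix,
    mu: float,
    nu: float,
    eps: float,
) -> float:
    Pc = np.clip(P, eps, None)
    logP = np.log(Pc)
    obj = 0.0
    if labeled.any():
        Rc = np.clip(R[labeled], eps, None)
        obj += float(np.sum(Rc * (np.log(Rc) - logP[labeled])))
    if mu > 0:
        deg = np.asarray(W.sum(axis=1)).ravel()
        cross = float(np.sum(Pc * (W @ logP)))
        self_term = float(deg @ np.sum(Pc * logP, axis=1))
        obj += mu * (self_term - cross)
    if nu != 0:
        obj += nu * float(np.sum(Pc * logP))  # -nu * H
    return obj


def objective(
    pt: ProbabilityTable, graph: NeighborGraph, params: SoftSLParams
) -> float:
    """Evaluate the misalignment functional C1 at pt."""
    if graph.n_nodes != pt.p.shape[0]:
        raise ValueError("graph and probability table disagree on n_docs")
    W = graph.to_sparse()
    return _objective_arrays(
        pt.p, pt.r, pt.labeled, W, params.mu, params.nu, params.eps
    )


def _gradient(
    P: np.ndarray,
    R: np.ndarray,
    labeled: np.ndarray,
    W: sp.csr_matrix,
    Wt: sp.csr_matrix,
    deg_out: np.ndarray,
    mu: float,
    nu: float,
    eps: float,
) -> np.ndarray:
    Pc = np.clip(P, eps, None)
    logP = np.log(Pc)
    G = np.zeros_like(P)
    G[labeled] -= np.clip(R[labeled], eps, None) / Pc[labeled]
    if mu > 0:
        G += mu * (deg_out[:, None] * (logP + 1.0) - (W @ logP))
        G -= mu * (Wt @ Pc) / Pc
    if nu != 0:
        G += nu * (logP + 1.0)
    return G


def minimize(
    pt0: ProbabilityTable, graph: NeighborGraph, params: SoftSLParams
) -> SoftSLResult:
    """Minimize C1 from pt0 by monotone exponentiated-gradient descent.

    Each step multiplies every row elementwise by exp(-eta * grad) and
    renormalizes; eta backtracks (halving) until the objective does not
    increase, so the recorded trace is non-increasing.  Stops when the
    relative objective decrease falls below ``tol`` or at ``max_iter``.
    """
    if graph.n_nodes != pt0.p.shape[0]:
        raise ValueError("graph and probability table disagree on n_docs")
    W = graph.to_sparse()
    Wt = sp.csr_matrix(W.T)
    deg_out = np.asarray(W.sum(axis=1)).ravel()
    P = pt0.p.copy()
    R, labeled = pt0.r, pt0.labeled
    mu, nu, eps = params.mu, params.nu, params.eps

    obj = _objective_arrays(P, R, labeled, W, mu, nu, eps)
    trace = [obj]
    eta = 1.0
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        G = _gradient(P, R, labeled, W, Wt, deg_out, mu, nu, eps)
        accepted = False
        while eta > 1e-14:
            E = -eta * G
            E -= E.max(axis=1, keepdims=True)  # row shift: invariant on simplex
            cand = np.clip(P, eps, None) * np.exp(E)
            cand /= cand.sum(axis=1, keepdims=True)
            cand_obj = _objective_arrays(cand, R, labeled, W, mu, nu, eps)
            if cand_obj <= obj:
                accepted = True
                break
            eta *= 0.5
        if not accepted:
            converged = True  # no descent direction at machine precision
            break
        delta = obj - cand_obj
        P, obj = cand, cand_obj
        trace.append(obj)
        eta = min(eta * 1.5, 1e6)
        if delta <= params.tol * max(1.0, abs(obj)):
            converged = True
            break

    table = ProbabilityTable(p=P, r=R.copy(), labeled=labeled.copy())
    return SoftSLResult(
        table=table, trace=np.asarray(trace), converged=converged, n_iter=it
    )


def restore_softsl(
    X: sp.spmatrix,
    Y: sp.spmatrix,
    params: SoftSLParams,
    graph: NeighborGraph | None = None,
) -> RelevancePairs:
    """Propose missing pairs: {(i, j): p_i^j >= T and Y[i, j] = 0}."""
    Y = sp.csr_matrix(Y, dtype=np.int8)
    if graph is None:
        graph = build_graph(X, params.k)
    pt0 = ProbabilityTable.from_labels(Y)
    result = minimize(pt0, graph, params)
    P = result.table.p
    unlabeled = np.asarray(Y.todense()) == 0
    hit = (P >= params.T) & unlabeled
    ds, cls_ = np.nonzero(hit)
    pairs = {(int(d), int(l)) for d, l in zip(ds, cls_)}
    scores = {(int(d), int(l)): float(P[d, l]) for d, l in zip(ds, cls_)}
    return RelevancePairs(pairs=pairs, scores=scores)
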