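"""End-to-end experimental protocol: corrupt -> restore -> modify -> train
-> evaluate.

For each deletion fraction p, a completely labeled training set is
corrupted, restoration parameters (k, T) are grid-searched on a dev split
carved from the corrupted training set (20% by default; dev labels are the
corrupted ones — the realistic regime with no oracle leakage), the
training set is modified in "add" or "del" mode with the winning pair set,
a Binary-Relevance classifier is trained on the modified set, and
micro-averaged metrics are reported on a held-out test set with complete
labels.  The p = 0 unmodified run is the reference row.

During grid search the restorer is fit on train-minus-dev (neighbor votes
come only from those documents) and scored on the whole training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .br import TrainConfig, predict, train_br
from .corruption import DeletionSpec, delete_labels
from .evaluation import micro_prf
from .graph import NeighborGraph, build_graph
from .modification import RelevancePairs, apply_add, apply_del
from .softsl import SoftSLParams, restore_softsl
from .synthetic import SyntheticSpec, generate
from .wknn import WkNNParams, restore_wknn

_RESTORERS = ("wknn", "softsl", "none")
_MODES = ("add", "del", "none")


@dataclass
class ExperimentConfig:
    """One experimental arm over a grid of deletion fractions."""

    data: tuple[sp.spmatrix, sp.spmatrix] | None = None
    synthetic: SyntheticSpec | None = None
    p_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    restorer: str = "wknn"
    mode: str = "add"
    k_grid: tuple[int, ...] = (5, 10, 15, 20)
    T_grid: tuple[float, ...] = (0.05, 0.1, 0.15, 0.25, 0.3, 0.5)
    mu: float = 0.5
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    dev_fraction: float = 0.2
    test_fraction: float = 1.0 / 3.0
    dev_labels: str = "corrupted"  # or "clean"
    include_baseline: bool = True  # the p = 0 unmodified reference row
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.data is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of data / synthetic")
        if self.restorer not in _RESTORERS:
            raise ValueError(f"restorer must be one of {_RESTORERS}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if (self.restorer == "none") != (self.mode == "none"):
            raise ValueError("restorer and mode must be 'none' together")
        if not self.k_grid or not self.T_grid or not self.p_grid:
            raise ValueError("grids must be nonempty")
        if not 0.0 < self.dev_fraction <= 0.5:
            raise ValueError("dev_fraction must be in (0, 0.5]")
        if self.dev_labels not in ("corrupted", "clean"):
            raise ValueError("dev_labels must be 'corrupted' or 'clean'")


def build_graph_restricted(
    X: sp.spmatrix, candidates: np.ndarray, k: int
) -> NeighborGraph:
    """k-NN graph whose neighbor pool is restricted to ``candidates``.

    Every row of X gets its k most cosine-similar documents among the
    candidate set (self excluded); indices are global row ids.  Used during
    grid search so dev documents never vote.
    """
    X = sp.csr_matrix(X, dtype=np.float64)
    candidates = np.asarray(candidates, dtype=np.int64)
    n = X.shape[0]
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    scale = np.where(norms == 0, 1.0, norms)
    Xn = sp.csr_matrix(sp.diags(1.0 / scale) @ X)
    S = np.asarray((Xn @ Xn[candidates].T).todense())  # (n, n_cand)
    # exclude self-similarity where a row is its own candidate
    pos_of = {int(c): j for j, c in enumerate(candidates)}
    for i in range(n):
        j = pos_of.get(i)
        if j is not None:
            S[i, j] = -np.inf
    col_rank = np.arange(candidates.size)
    idx_rows, w_rows = [], []
    for i in range(n):
        row = S[i]
        order = np.lexsort((col_rank, -row))
        take = [j for j in order if np.isfinite(row[j])][:k]
        idx_rows.append(candidates[take])
        w_rows.append(row[take])
    k_eff = min(len(r) for r in idx_rows)
    indices = np.vstack([r[:k_eff] for r in idx_rows]).astype(np.int64)
    weights = np.vstack([r[:k_eff] for r in w_rows]).astype(np.float64)
    return NeighborGraph(k=k_eff, indices=indices, weights=weights)


def _restore(
    cfg: ExperimentConfig,
    X: sp.spmatrix,
    Y: sp.spmatrix,
    k: int,
    T: float,
    graph: NeighborGraph,
) -> RelevancePairs:
    if cfg.restorer == "wknn":
        return restore_wknn(X, Y, WkNNParams(k=graph.k, T=T), graph=graph)
    params = SoftSLParams(k=graph.k, mu=cfg.mu, T=T)
    return restore_softsl(X, Y, params, graph=graph)


def _train_eval(
    cfg: ExperimentConfig,
    X_fit: sp.spmatrix,
    Y_fit: sp.spmatrix,
    mask,
    X_eval: sp.spmatrix,
    Y_eval: sp.spmatrix,
):
    model = train_br(X_fit, Y_fit, mask=mask, cfg=cfg.train_cfg)
    return micro_prf(Y_eval, predict(model, X_eval))


def _subset_mask(mask, rows: np.ndarray):
    """Restrict a NegativeMask to a row subset, reindexing to local ids."""
    if mask is None:
        return None
    from .modification import NegativeMask

    local = {int(g): i for i, g in enumerate(rows)}
    out: dict[int, set[int]] = {}
    for l, docs in mask.masks.items():
        kept = {local[d] for d in docs if d in local}
        if kept:
            out[l] = kept
    return NegativeMask(masks=out)


def _modified_training(cfg, Y_corrupt, pairs):
    """Apply the configured modification; returns (Y_train, mask)."""
    if cfg.mode == "add":
        return apply_add(Y_corrupt, pairs), None
    if cfg.mode == "del":
        return Y_corrupt, apply_del(Y_corrupt, pairs)
    return Y_corrupt, None


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full protocol; one result row per deletion fraction.

    Columns: p, restorer, mode, k_star, T_star, dev_f1, n_proposed,
    n_deleted, n_recovered, precision, recall, f1.  A p = 0 reference row
    (no corruption, no modification) is included when
    ``cfg.include_baseline``.
    """
    if cfg.synthetic is not None:
        X, Y = generate(cfg.synthetic)
    else:
        X, Y = (sp.csr_matrix(cfg.data[0]), sp.csr_matrix(cfg.data[1], dtype=np.int8))
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_test = int(round(cfg.test_fraction * n))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    X_tr, Y_tr = X[train_idx], Y[train_idx]
    X_te, Y_te = X[test_idx], Y[test_idx]

    n_tr = X_tr.shape[0]
    dev_rng = np.random.default_rng(cfg.seed + 1)
    dev_perm = dev_rng.permutation(n_tr)
    n_dev = int(round(cfg.dev_fraction * n_tr))
    dev_rows = np.sort(dev_perm[:n_dev])
    core_rows = np.sort(dev_perm[n_dev:])

    rows = []
    if cfg.include_baseline:
        mm = _train_eval(cfg, X_tr, Y_tr, None, X_te, Y_te)
        rows.append(
            dict(p=0.0, restorer="none", mode="none", k_star=np.nan,
                 T_star=np.nan, dev_f1=np.nan, n_proposed=0, n_deleted=0,
                 n_recovered=0, precision=mm.precision, recall=mm.recall,
                 f1=mm.f1)
        )

    for p in cfg.p_grid:
        Y_corrupt, deleted, _ = delete_labels(
            Y_tr, DeletionSpec(p=p, seed=cfg.seed + int(round(1000 * p)))
        )
        if cfg.restorer == "none":
            mm = _train_eval(cfg, X_tr, Y_corrupt, None, X_te, Y_te)
            rows.append(
                dict(p=p, restorer="none", mode="none", k_star=np.nan,
                     T_star=np.nan, dev_f1=np.nan, n_proposed=0,
                     n_deleted=len(deleted), n_recovered=0,
                     precision=mm.precision, recall=mm.recall, f1=mm.f1)
            )
            continue

        Y_dev_eval = (Y_tr if cfg.dev_labels == "clean" else Y_corrupt)[dev_rows]
        best = None  # (dev_f1, -k, T, k, T) with ties -> smaller k, larger T
        for k in cfg.k_grid:
            grid_graph = build_graph_restricted(X_tr, core_rows, k)
            for T in sorted(cfg.T_grid, reverse=True):
                pairs = _restore(cfg, X_tr, Y_corrupt, k, T, grid_graph)
                Y_mod, mask = _modified_training(cfg, Y_corrupt, pairs)
                mm = _train_eval(
                    cfg,
                    X_tr[core_rows],
                    Y_mod[core_rows],
                    _subset_mask(mask, core_rows),
                    X_tr[dev_rows],
                    Y_dev_eval,
                )
                key = (mm.f1, -k, T)
                if best is None or key > best[0]:
                    best = (key, k, T)
        _, k_star, T_star = best

        final_graph = build_graph(X_tr, k_star)
        pairs = _restore(cfg, X_tr, Y_corrupt, k_star, T_star, final_graph)
        Y_mod, mask = _modified_training(cfg, Y_corrupt, pairs)
        mm = _train_eval(cfg, X_tr, Y_mod, mask, X_te, Y_te)
        recovered = len(pairs.pairs & deleted)
        rows.append(
            dict(p=p, restorer=cfg.restorer, mode=cfg.mode, k_star=k_star,
                 T_star=T_star, dev_f1=best[0][0], n_proposed=len(pairs),
                 n_deleted=len(deleted), n_recovered=recovered,
                 precision=mm.precision, recall=mm.recall, f1=mm.f1)
        )
    return pd.DataFrame(rows)
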