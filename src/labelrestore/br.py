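"""Binary-Relevance multilabel classification with per-label thresholds.

An m-label problem is decomposed into m independent binary problems.  Each
label l gets its own scorer — a linear large-margin classifier (decision
value w_l . x + intercept) or a random forest (positive-vote fraction; 30
trees, sqrt-of-features split candidates by default) — plus a
classification threshold b_l: a document is assigned label l iff
score_l(x) > b_l.

"del"-mode training honors a :class:`~labelrestore.modification.NegativeMask`:
masked documents are dropped from label l's negatives (they stay in every
other label's problem), so the binary problem for l has exactly
n - |mask[l]| instances.

Tuning follows a two-level protocol: the shared cost parameter C is varied
on a grid; for every C the per-label thresholds b_l are scanned over
cut-points of the sorted dev-set scores; the (C, {b_l}) maximizing the
configured F1 aggregate on the dev set wins (ties: smaller C, then smaller
b_l).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

_BASES = ("linear-svm", "random-forest")
_TUNE_METRICS = ("micro", "doc-f1")


@dataclass
class TrainConfig:
    """Base learner and tuning protocol for Binary Relevance."""

    base: str = "linear-svm"
    C: float = 1.0
    C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    n_trees: int = 30
    cv_folds: int = 5
    seed: int = 0
    tune_metric: str = "micro"

    def __post_init__(self) -> None:
        if self.base not in _BASES:
            raise ValueError(f"base must be one of {_BASES}")
        if not self.C_grid:
            raise ValueError("C grid must be nonempty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.tune_metric not in _TUNE_METRICS:
            raise ValueError(f"tune_metric must be one of {_TUNE_METRICS}")


class _ConstantScorer:
    """Degenerate per-label scorer for single-class binary problems."""

    def __init__(self, value: float):
        self.value = value

    def score(self, X) -> np.ndarray:
        return np.full(X.shape[0], self.value)


@dataclass
class BRModel:
    """One scorer and one threshold b_l per label; shared C (linear case)."""

    base: str
    scorers: list
    thresholds: np.ndarray
    C: float
    n_features: int
    label_names: list[str] = field(default_factory=list)

    @property
    def n_labels(self) -> int:
        return len(self.scorers)


def _fit_one(X, y: np.ndarray, cfg: TrainConfig, label_seed: int):
    classes = np.unique(y)
    if classes.size == 1:
        # no positives -> always-negative; no negatives -> always-positive
        return _ConstantScorer(1.0 if classes[0] == 1 else -1.0)
    if cfg.base == "linear-svm":
        clf = LinearSVC(C=cfg.C, random_state=label_seed, max_iter=20000, tol=1e-5)
    else:
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_features="sqrt",
            random_state=label_seed,
            n_jobs=1,
        )
    clf.fit(X, y)
    return clf


def train_br(
    X: sp.spmatrix,
    Y: sp.spmatrix,
    mask=None,
    cfg: TrainConfig = TrainConfig(),
    label_names: list[str] | None = None,
) -> BRModel:
    """Fit one binary scorer per label, honoring a del-mode negative mask.

    Label l's binary problem: positives {d: Y[d,l]=1}; negatives
    {d: Y[d,l]=0} minus mask[l].  Labels with no positives get an
    always-negative scorer (logged).
    """
    X = sp.csr_matrix(X, dtype=np.float64)
    Y = sp.csr_matrix(Y, dtype=np.int8)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    n, m = Y.shape
    Yd = np.asarray(Y.todense())
    scorers = []
    default_thr = 0.0 if cfg.base == "linear-svm" else 0.5
    for l in range(m):
        y = Yd[:, l]
        keep = np.ones(n, dtype=bool)
        if mask is not None:
            masked = np.fromiter(mask.docs_for(l), dtype=int, count=-1) \
                if mask.docs_for(l) else np.array([], dtype=int)
            # masked docs are negatives by construction; drop them
            keep[masked] = False
            keep[y == 1] = True
        if y[keep].sum() == 0:
            logger.info("label %d has no positives; always-negative scorer", l)
        scorers.append(_fit_one(X[keep], y[keep], cfg, cfg.seed + l))
    return BRModel(
        base=cfg.base,
        scorers=scorers,
        thresholds=np.full(m, default_thr),
        C=cfg.C,
        n_features=X.shape[1],
        label_names=label_names or [f"label_{j}" for j in range(m)],
    )


def predict_scores(model: BRModel, X: sp.spmatrix) -> np.ndarray:
    """n x m real score table: decision values (linear) or vote fractions."""
    X = sp.csr_matrix(X, dtype=np.float64)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.n_features}"
        )
    cols = []
    for scorer in model.scorers:
        if isinstance(scorer, _ConstantScorer):
            cols.append(scorer.score(X))
        elif hasattr(scorer, "decision_function"):
            cols.append(scorer.decision_function(X))
        else:
            proba = scorer.predict_proba(X)
            pos_col = int(np.flatnonzero(scorer.classes_ == 1)[0])
            cols.append(proba[:, pos_col])
    return np.column_stack(cols)


def predict(model: BRModel, X: sp.spmatrix) -> sp.csr_matrix:
    """Binary predictions: label l assigned iff score > b_l."""
    S = predict_scores(model, X)
    return sp.csr_matrix((S > model.thresholds[None, :]).astype(np.int8))


# ---------------------------------------------------------------------------
# threshold / C tuning


def _f1_counts(tp: float, fp: float, fn: float) -> float:
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def threshold_candidates(scores: np.ndarray) -> np.ndarray:
    """Cut-points of a score column: midpoints between sorted unique scores
    plus one candidate below the minimum (assign-all) and one above the
    maximum (assign-none)."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - 1.0], mids, [u[-1] + 1.0]))


def best_threshold(scores: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Scan cut-points for the b maximizing binary F1 (ties: smaller b)."""
    best_b, best_f1 = None, -1.0
    pos = truth == 1
    for b in threshold_candidates(scores):
        pred = scores > b
        tp = float(np.sum(pred & pos))
        fp = float(np.sum(pred & ~pos))
        fn = float(np.sum(~pred & pos))
        f1 = _f1_counts(tp, fp, fn)
        if f1 > best_f1 + 1e-12:
            best_b, best_f1 = float(b), f1
    return best_b, best_f1


def _aggregate_f1(truth: np.ndarray, pred: np.ndarray, metric: str) -> float:
    if metric == "micro":
        tp = float(np.sum(pred & (truth == 1)))
        fp = float(np.sum(pred & (truth == 0)))
        fn = float(np.sum(~pred & (truth == 1)))
        return _f1_counts(tp, fp, fn)
    # doc-f1: mean over documents of per-document F1
    vals = []
    for i in range(truth.shape[0]):
        tp = float(np.sum(pred[i] & (truth[i] == 1)))
        fp = float(np.sum(pred[i] & (truth[i] == 0)))
        fn = float(np.sum(~pred[i] & (truth[i] == 1)))
        vals.append(_f1_counts(tp, fp, fn))
    return float(np.mean(vals))


def tune(
    X: sp.spmatrix,
    Y: sp.spmatrix,
    dev_X: sp.spmatrix,
    dev_Y: sp.spmatrix,
    cfg: TrainConfig,
    mask=None,
) -> tuple[float, np.ndarray, float]:
    """Grid-search C and per-label thresholds b_l on a dev set.

    For each C on ``cfg.C_grid``, a Binary-Relevance model is fit on
    (X, Y); each b_l is chosen by scanning dev-score cut-points for the
    best per-label F1; the (C, {b_l}) with the highest aggregate dev F1
    (``cfg.tune_metric``) is returned as ``(C*, b*, best_f1)``.
    Ties prefer smaller C, then smaller b_l.
    """
    dev_Yd = np.asarray(sp.csr_matrix(dev_Y, dtype=np.int8).todense())
    if dev_Yd.shape[0] == 0:
        raise ValueError("dev set is empty")
    if dev_Yd.sum() == 0:
        raise ValueError("dev set has no positive labels; cannot tune")
    best: tuple[float, np.ndarray, float] | None = None
    for C in cfg.C_grid:
        cfg_c = TrainConfig(
            base=cfg.base, C=C, C_grid=cfg.C_grid, n_trees=cfg.n_trees,
            cv_folds=cfg.cv_folds, seed=cfg.seed, tune_metric=cfg.tune_metric,
        )
        model = train_br(X, Y, mask=mask, cfg=cfg_c)
        S = predict_scores(model, dev_X)
        b = np.array(
            [best_threshold(S[:, l], dev_Yd[:, l])[0] for l in range(S.shape[1])]
        )
        pred = S > b[None, :]
        f1 = _aggregate_f1(dev_Yd, pred, cfg.tune_metric)
        if best is None or f1 > best[2] + 1e-12:
            best = (C, b, f1)
    assert best is not None
    return best
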