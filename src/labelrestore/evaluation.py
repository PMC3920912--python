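"""Micro-averaged precision/recall/F1 and CROC curves.

Micro-averaging pools true/false positives and false negatives over all
(document, label) cells before taking ratios, so frequent labels dominate
— the standard multilabel summary.

A CROC curve is a ROC curve whose false-positive axis is rescaled by
x_new(x) = (1 - e^(-a*x)) / (1 - e^(-a)) to magnify the early-retrieval
region; the default a = 7.  AUC is the integral of tpr with respect to
x_new along the ROC polyline (tied scores move together; segments are
linear in the original fpr axis and integrated in closed form after the
rescale); as a -> 0+ the rescaling tends to the identity and CROC AUC
converges to ordinary ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True)
class MicroMetrics:
    """Pooled cell counts and the derived precision/recall/F1."""

    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float


def micro_prf(Y_true: sp.spmatrix, Y_pred: sp.spmatrix) -> MicroMetrics:
    """Micro-averaged precision, recall and F1 over all cells."""
    T = sp.csr_matrix(Y_true, dtype=np.int8)
    P = sp.csr_matrix(Y_pred, dtype=np.int8)
    if T.shape != P.shape:
        raise ValueError(f"shape mismatch: truth {T.shape} vs prediction {P.shape}")
    tp = int(T.multiply(P).sum())
    fp = int(P.sum()) - tp
    fn = int(T.sum()) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MicroMetrics(TP=tp, FP=fp, FN=fn,
                        precision=precision, recall=recall, f1=f1)


def croc_rescale(x: float | np.ndarray, alpha: float = 7.0):
    """Exponential magnification of the false-positive axis.

    x_new(0) = 0, x_new(1) = 1; strictly increasing and concave for a > 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=np.float64)
    if (x < 0).any() or (x > 1).any():
        raise ValueError("x must lie in [0, 1]")
    out = -np.expm1(-alpha * x) / -np.expm1(-alpha)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CROCCurve:
    """Rescaled ROC points and the trapezoidal AUC on the rescaled axis."""

    alpha: float
    x_new: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _roc_points(scores: np.ndarray, truth: np.ndarray):
    # descending-score sweep; tied scores move together
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order].astype(np.float64)
    n_pos = t.sum()
    n_neg = t.size - n_pos
    tp = np.cumsum(t)
    fp = np.cumsum(1.0 - t)
    last_of_tie = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last_of_tie] / n_pos]
    fpr = np.r_[0.0, fp[last_of_tie] / n_neg]
    return fpr, tpr


def _segment_auc(x0, x1, y0, y1, alpha):
    """Integral of tpr d(x_new) over one ROC segment, in closed form.

    On [x0, x1] the polyline is tpr(x) = a + b*x and
    d(x_new) = alpha*e^(-alpha*x)/(1 - e^(-alpha)) dx, so

        int = [ e^(-a x0)(a + b x0) - e^(-a x1)(a + b x1)
                + (b/alpha) * e^(-a x0) * (1 - e^(-alpha (x1-x0))) ]
              / (1 - e^(-alpha))
    """
    if x1 == x0:
        return 0.0
    b = (y1 - y0) / (x1 - x0)
    a = y0 - b * x0
    e0 = np.exp(-alpha * x0)
    e1 = np.exp(-alpha * x1)
    num = e0 * (a + b * x0) - e1 * (a + b * x1)
    num += (b / alpha) * e0 * (-np.expm1(-alpha * (x1 - x0)))
    return num / -np.expm1(-alpha)


def croc_curve(
    scores: np.ndarray, truth: np.ndarray, alpha: float = 7.0
) -> CROCCurve:
    """CROC curve and AUC for one label's per-document scores.

    Requires at least one positive and one negative in ``truth``.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth).ravel().astype(np.int8)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if truth.min() == truth.max():
        raise ValueError("truth must contain both a positive and a negative")
    fpr, tpr = _roc_points(scores, truth)
    x = croc_rescale(fpr, alpha)
    auc = float(sum(
        _segment_auc(fpr[i], fpr[i + 1], tpr[i], tpr[i + 1], alpha)
        for i in range(len(fpr) - 1)
    ))
    return CROCCurve(alpha=alpha, x_new=x, tpr=tpr, fpr=fpr, auc=auc)
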