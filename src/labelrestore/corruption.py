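"""Simulate incompletely labeled training sets by controlled label deletion.

Starting from a completely labeled binary label matrix, a fraction ``p`` of
each class's positive labels is deleted at random, subject to two rules:
the per-class deletion count is ``round(p * positives(class))`` so the
class-size distribution is preserved, and every document keeps at least one
label.  Deletions blocked by the keep-one rule are reported as shortfalls
rather than redistributed to other classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass(frozen=True)
class DeletionSpec:
    """Deletion fraction ``p`` in [0, 1) and RNG seed.

    ``rounding='half-up'`` deletes round(p*n_cl) labels per class (the
    default, floor(x+0.5)); ``rounding='floor'`` deletes floor(p*n_cl).
    """

    p: float
    seed: int = 0
    rounding: str = "half-up"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 1.0:
            raise ValueError("deletion fraction p must be in [0, 1)")
        if self.rounding not in ("half-up", "floor"):
            raise ValueError("rounding must be 'half-up' or 'floor'")


def _round(x: float, mode: str) -> int:
    return int(np.floor(x + 0.5)) if mode == "half-up" else int(np.floor(x))


def delete_labels(
    Y: sp.spmatrix, spec: DeletionSpec
) -> tuple[sp.csr_matrix, set[tuple[int, int]], dict[int, int]]:
    """Delete a per-class fraction ``p`` of positive labels.

    Parameters
    ----------
    Y
        Binary label matrix whose every row has >= 1 positive.
    spec
        Deletion fraction, seed, rounding mode.

    Returns
    -------
    Y_incomplete : csr_matrix
        ``Y`` with the sampled positives flipped to 0; every row still has
        >= 1 positive.
    deleted : set of (doc, label)
        The removed pairs.
    shortfall : dict label -> count
        Per-class deletions blocked by the keep-one-label constraint
        (absent classes met their quota exactly).

    Classes are visited in seeded random order; within a class candidate
    positives are drawn uniformly without replacement, skipping any whose
    removal would empty its row.
    """
    Y = sp.csr_matrix(Y, dtype=np.int8)
    row_pos = np.asarray(Y.sum(axis=1)).ravel()
    if (row_pos == 0).any():
        raise ValueError("every row of Y must have at least one positive label")

    dense = Y.toarray().astype(bool)
    n_docs, n_labels = dense.shape
    remaining = row_pos.astype(np.int64).copy()
    rng = np.random.default_rng(spec.seed)

    deleted: set[tuple[int, int]] = set()
    shortfall: dict[int, int] = {}

    if spec.p == 0.0:
        return Y.copy(), deleted, shortfall

    for cl in rng.permutation(n_labels):
        cl = int(cl)
        docs = np.flatnonzero(dense[:, cl])
        quota = _round(spec.p * docs.size, spec.rounding)
        if quota == 0:
            continue
        removed = 0
        for d in rng.permutation(docs):
            if removed == quota:
                break
            d = int(d)
            if remaining[d] <= 1:
                continue  # keep-one-label constraint
            dense[d, cl] = False
            remaining[d] -= 1
            deleted.add((d, cl))
            removed += 1
        if removed < quota:
            shortfall[cl] = quota - removed

    if shortfall:
        warnings.warn(
            f"keep-one-label constraint blocked {sum(shortfall.values())} "
            f"deletion(s) across {len(shortfall)} class(es)"
        )
    Y_inc = sp.csr_matrix(dense.astype(np.int8))
    return Y_inc, deleted, shortfall
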