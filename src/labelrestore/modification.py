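"""Apply restored (document, label) pairs to the training set.

Restoration yields a pair set PC of labels the annotators likely missed.
Two modification modes consume it:

``add``
    flip every proposed pair to positive (elementwise OR into Y);
``del``
    leave Y untouched but exclude each proposed document from the negative
    examples of the proposed label during per-label training, via a
    :class:`NegativeMask`.

Annotator-assigned positives are never removed in either mode: only
missing labels occur in this corruption model, never spurious ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

Pair = tuple[int, int]


@dataclass
class RelevancePairs:
    """A set of (doc, label) pairs proposed as missing, with scores."""

    pairs: set[Pair] = field(default_factory=set)
    scores: dict[Pair, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Pair) -> bool:
        return pair in self.pairs

    def __iter__(self):
        return iter(sorted(self.pairs))

    def validate(self, n_docs: int, n_labels: int) -> None:
        for d, l in self.pairs:
            if not (0 <= d < n_docs and 0 <= l < n_labels):
                raise ValueError(f"pair ({d}, {l}) out of range "
                                 f"({n_docs} docs, {n_labels} labels)")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("doc_id\tlabel_id\tscore\n")
            for d, l in self:
                fh.write(f"{d}\t{l}\t{self.scores.get((d, l), float('nan')):.17g}\n")

    @classmethod
    def from_tsv(cls, path) -> "RelevancePairs":
        pairs: set[Pair] = set()
        scores: dict[Pair, float] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("doc_id"):
                raise ValueError(f"{path}: missing doc_id/label_id header")
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                d, l = int(parts[0]), int(parts[1])
                pairs.add((d, l))
                if len(parts) > 2:
                    scores[(d, l)] = float(parts[2])
        return cls(pairs=pairs, scores=scores)


@dataclass
class NegativeMask:
    """Per-label doc sets withheld from that label's negatives at training."""

    masks: dict[int, set[int]] = field(default_factory=dict)

    def docs_for(self, label: int) -> set[int]:
        return self.masks.get(label, set())

    def total(self) -> int:
        return sum(len(s) for s in self.masks.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label_id\tdoc_id\n")
            for l in sorted(self.masks):
                for d in sorted(self.masks[l]):
                    fh.write(f"{l}\t{d}\n")

    @classmethod
    def from_tsv(cls, path) -> "NegativeMask":
        masks: dict[int, set[int]] = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                l, d = (int(v) for v in line.split("\t"))
                masks.setdefault(l, set()).add(d)
        return cls(masks=masks)


def apply_add(Y: sp.spmatrix, pc: RelevancePairs) -> sp.csr_matrix:
    """Return Y with every proposed pair set positive (monotone, idempotent)."""
    Y = sp.csr_matrix(Y, dtype=np.int8)
    pc.validate(*Y.shape)
    if not pc.pairs:
        return Y.copy()
    rows, cols = zip(*sorted(pc.pairs))
    add = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=Y.shape
    )
    out = Y.maximum(add)
    return sp.csr_matrix(out, dtype=np.int8)


def apply_del(Y: sp.spmatrix, pc: RelevancePairs) -> NegativeMask:
    """Build the del-mode mask: proposed pairs that are currently negative.

    Y is not modified; pairs already positive need no exclusion and are
    dropped.
    """
    Y = sp.csr_matrix(Y, dtype=np.int8)
    pc.validate(*Y.shape)
    Yd = Y.toarray()
    masks: dict[int, set[int]] = {}
    for d, l in pc.pairs:
        if Yd[d, l] == 0:
            masks.setdefault(l, set()).add(d)
    return NegativeMask(masks=masks)
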