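"""Data model and I/O for multilabel datasets.

A dataset is a pair (X, Y): a nonnegative feature matrix X (n_docs x
n_features) and a binary label matrix Y (n_docs x n_labels).  Both are held
as scipy CSR matrices; density is never assumed.  Three on-disk dialects
are supported, all plain text:

``mulan-arff``
    ``<base>.arff`` — dense ARFF whose last ``m`` numeric attributes are the
    binary labels; ``<base>.xml`` — Mulan-style companion XML listing the
    label attribute names in order.
``pair-tsv+mtx``
    ``<base>.mtx`` — MatrixMarket sparse feature matrix; ``<base>.pairs.tsv``
    — two-column ``doc_id<TAB>label_id`` positive-pair list; a header line
    ``#n_docs=<n> n_labels=<m>`` pins the shape.
``dense-tsv``
    ``<base>.features.tsv`` and ``<base>.labels.tsv`` — dense tab-separated
    matrices, one document per row, no header.

Label columns keep the order of first appearance in the source file; the
ARFF/XML pair persists that order so runs are reproducible.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

FORMATS = ("mulan-arff", "pair-tsv+mtx", "dense-tsv")


class MultilabelIOError(ValueError):
    """Malformed multilabel dataset file."""


@dataclass
class MultilabelDataset:
    """Feature matrix + binary label matrix + label names.

    ``X`` is CSR float, nonnegative; ``Y`` is CSR with {0,1} entries.
    """

    X: sp.csr_matrix
    Y: sp.csr_matrix
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X, dtype=np.float64)
        self.Y = sp.csr_matrix(self.Y, dtype=np.int8)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"feature rows ({self.X.shape[0]}) != label rows ({self.Y.shape[0]})"
            )
        if not self.label_names:
            self.label_names = [f"label_{j}" for j in range(self.Y.shape[1])]
        if len(self.label_names) != self.Y.shape[1]:
            raise ValueError("label_names length != number of label columns")
        if self.X.nnz and not np.all(np.isfinite(self.X.data)):
            raise ValueError("feature matrix contains non-finite values")
        if self.Y.nnz and not np.all(np.isin(self.Y.data, (0, 1))):
            raise ValueError("label matrix entries must be binary")

    @property
    def n_docs(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_labels(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class DatasetSplit:
    """Pairwise-disjoint train / dev / test index sets."""

    train_indices: np.ndarray
    dev_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        tr = set(np.asarray(self.train_indices).tolist())
        dv = set(np.asarray(self.dev_indices).tolist())
        te = set(np.asarray(self.test_indices).tolist())
        if tr & dv or tr & te or dv & te:
            raise ValueError("train/dev/test index sets must be pairwise disjoint")


def validate_training_labels(Y: sp.spmatrix) -> None:
    """Reject label matrices with unlabeled rows in a training role.

    Every training document must carry at least one label; test-role label
    matrices (prediction targets) are exempt from this check.
    """
    row_pos = np.asarray(sp.csr_matrix(Y).sum(axis=1)).ravel()
    bad = np.flatnonzero(row_pos == 0)
    if bad.size:
        raise MultilabelIOError(
            f"training label matrix has {bad.size} row(s) with zero labels "
            f"(first: doc {int(bad[0])})"
        )


def label_stats(Y: sp.spmatrix) -> tuple[float, float]:
    """Mean labels per document and mean documents per label.

    Returns ``(total positives / n_docs, total positives / n_labels)`` —
    the two training-set summary statistics reported alongside modification
    results.
    """
    Y = sp.csr_matrix(Y)
    total = float(Y.sum())
    return total / Y.shape[0], total / Y.shape[1]


def train_test_split_indices(
    n_docs: int, test_fraction: float, seed: int
) -> DatasetSplit:
    """Random train/test partition (dev carved later from train)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_docs)
    n_test = int(round(test_fraction * n_docs))
    return DatasetSplit(
        train_indices=np.sort(perm[n_test:]),
        dev_indices=np.array([], dtype=int),
        test_indices=np.sort(perm[:n_test]),
    )


# ---------------------------------------------------------------------------
# readers / writers


def read_multilabel(
    path: str | Path, format: str, role: str = "train"
) -> MultilabelDataset:
    """Read a multilabel dataset from ``<base>`` files in the given format.

    ``role='train'`` enforces >=1 label per row; ``role='test'`` permits
    unlabeled rows (they are prediction targets).
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if role not in ("train", "test"):
        raise ValueError("role must be 'train' or 'test'")
    base = Path(path)
    if format == "mulan-arff":
        ds = _read_arff(base)
    elif format == "pair-tsv+mtx":
        ds = _read_pair_mtx(base)
    else:
        ds = _read_dense_tsv(base)
    if role == "train":
        validate_training_labels(ds.Y)
    return ds


def write_multilabel(ds: MultilabelDataset, path: str | Path, format: str) -> None:
    """Write ``ds`` to ``<base>`` files; inverse of :func:`read_multilabel`."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    if format == "mulan-arff":
        _write_arff(ds, base)
    elif format == "pair-tsv+mtx":
        _write_pair_mtx(ds, base)
    else:
        _write_dense_tsv(ds, base)


# -- Mulan-style ARFF -------------------------------------------------------

_ATTR_RE = re.compile(r"@attribute\s+(?:'([^']*)'|(\S+))\s+(\S+)", re.IGNORECASE)


def _read_arff(base: Path) -> MultilabelDataset:
    arff_path = base.with_suffix(".arff")
    xml_path = base.with_suffix(".xml")
    label_names = _read_label_xml(xml_path)
    attr_names: list[str] = []
    data_rows: list[list[float]] = []
    in_data = False
    for lineno, raw in enumerate(arff_path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            m = _ATTR_RE.match(line)
            if not m:
                raise MultilabelIOError(f"{arff_path}:{lineno}: malformed @attribute")
            attr_names.append(m.group(1) or m.group(2))
            continue
        if low.startswith("@data"):
            in_data = True
            continue
        if not in_data:
            raise MultilabelIOError(f"{arff_path}:{lineno}: data before @data section")
        fields = line.split(",")
        if len(fields) != len(attr_names):
            raise MultilabelIOError(
                f"{arff_path}:{lineno}: expected {len(attr_names)} fields, "
                f"got {len(fields)}"
            )
        try:
            data_rows.append([float(v) for v in fields])
        except ValueError as exc:
            raise MultilabelIOError(f"{arff_path}:{lineno}: {exc}") from None
    if not data_rows:
        raise MultilabelIOError(f"{arff_path}: no data rows")
    label_set = set(label_names)
    label_cols = [j for j, a in enumerate(attr_names) if a in label_set]
    if len(label_cols) != len(label_names):
        raise MultilabelIOError(
            f"{arff_path}: XML lists {len(label_names)} labels but only "
            f"{len(label_cols)} matching attributes found"
        )
    # keep XML order, which is the persisted order of first appearance
    col_of = {attr_names[j]: j for j in label_cols}
    feat_cols = [j for j in range(len(attr_names)) if j not in set(label_cols)]
    arr = np.asarray(data_rows, dtype=np.float64)
    X = arr[:, feat_cols]
    Y = arr[:, [col_of[name] for name in label_names]]
    if Y.size and not np.all(np.isin(Y, (0.0, 1.0))):
        raise MultilabelIOError(f"{arff_path}: non-binary label values")
    return MultilabelDataset(sp.csr_matrix(X), sp.csr_matrix(Y.astype(np.int8)),
                             list(label_names))


def _read_label_xml(xml_path: Path) -> list[str]:
    import xml.etree.ElementTree as ET

    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise MultilabelIOError(f"{xml_path}: {exc}") from None
    names = [el.attrib["name"] for el in root.iter() if el.tag.endswith("label")]
    if not names:
        raise MultilabelIOError(f"{xml_path}: no <label> elements")
    return names


def _write_arff(ds: MultilabelDataset, base: Path) -> None:
    arff_path = base.with_suffix(".arff")
    xml_path = base.with_suffix(".xml")
    lines = [f"@relation {base.stem}", ""]
    for j in range(ds.n_features):
        lines.append(f"@attribute feat_{j} numeric")
    for name in ds.label_names:
        lines.append(f"@attribute '{name}' {{0,1}}")
    lines.append("")
    lines.append("@data")
    Xd = ds.X.toarray()
    Yd = ds.Y.toarray()
    for i in range(ds.n_docs):
        feats = ",".join(repr(float(v)) for v in Xd[i])
        labs = ",".join(str(int(v)) for v in Yd[i])
        lines.append(f"{feats},{labs}" if feats else labs)
    arff_path.write_text("\n".join(lines) + "\n")
    xml_lines = ['<?xml version="1.0" encoding="utf-8"?>',
                 '<labels xmlns="http://mulan.sourceforge.net/labels">']
    xml_lines += [f'  <label name="{name}"></label>' for name in ds.label_names]
    xml_lines.append("</labels>")
    xml_path.write_text("\n".join(xml_lines) + "\n")


# -- MatrixMarket + pair TSV ------------------------------------------------

def _read_pair_mtx(base: Path) -> MultilabelDataset:
    mtx_path = base.with_suffix(".mtx")
    pairs_path = base.parent / (base.name + ".pairs.tsv")
    X = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    n_docs = X.shape[0]
    n_labels = None
    rows, cols = [], []
    label_names: list[str] = []
    for lineno, raw in enumerate(pairs_path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*n_docs=(\d+)\s+n_labels=(\d+)", line)
            if m:
                if int(m.group(1)) != n_docs:
                    raise MultilabelIOError(
                        f"{pairs_path}:{lineno}: header n_docs={m.group(1)} "
                        f"but feature matrix has {n_docs} rows"
                    )
                n_labels = int(m.group(2))
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise MultilabelIOError(
                f"{pairs_path}:{lineno}: expected 'doc_id<TAB>label_id'"
            )
        try:
            d, l = int(parts[0]), int(parts[1])
        except ValueError:
            raise MultilabelIOError(
                f"{pairs_path}:{lineno}: non-integer pair {parts!r}"
            ) from None
        if d < 0 or d >= n_docs:
            raise MultilabelIOError(f"{pairs_path}:{lineno}: doc id {d} out of range")
        rows.append(d)
        cols.append(l)
    if n_labels is None:
        n_labels = (max(cols) + 1) if cols else 0
    if cols and max(cols) >= n_labels:
        raise MultilabelIOError(
            f"{pairs_path}: label id {max(cols)} out of range (n_labels={n_labels})"
        )
    Y = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n_docs, n_labels)
    )
    Y.data[:] = 1  # collapse duplicate pairs
    return MultilabelDataset(X, Y, label_names)


def _write_pair_mtx(ds: MultilabelDataset, base: Path) -> None:
    scipy.io.mmwrite(str(base.with_suffix(".mtx")), sp.coo_matrix(ds.X))
    pairs_path = base.parent / (base.name + ".pairs.tsv")
    coo = sp.coo_matrix(ds.Y)
    order = np.lexsort((coo.col, coo.row))
    lines = [f"# n_docs={ds.n_docs} n_labels={ds.n_labels}"]
    lines += [f"{coo.row[i]}\t{coo.col[i]}" for i in order]
    pairs_path.write_text("\n".join(lines) + "\n")


# -- dense TSV --------------------------------------------------------------

def _read_dense_tsv(base: Path) -> MultilabelDataset:
    feat_path = base.parent / (base.name + ".features.tsv")
    lab_path = base.parent / (base.name + ".labels.tsv")
    try:
        X = np.loadtxt(str(feat_path), delimiter="\t", ndmin=2)
        Y = np.loadtxt(str(lab_path), delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise MultilabelIOError(f"{base}: {exc}") from None
    if Y.size and not np.all(np.isin(Y, (0.0, 1.0))):
        raise MultilabelIOError(f"{lab_path}: non-binary label values")
    return MultilabelDataset(sp.csr_matrix(X), sp.csr_matrix(Y.astype(np.int8)), [])


def _write_dense_tsv(ds: MultilabelDataset, base: Path) -> None:
    feat_path = base.parent / (base.name + ".features.tsv")
    lab_path = base.parent / (base.name + ".labels.tsv")
    np.savetxt(str(feat_path), ds.X.toarray(), delimiter="\t", fmt="%.17g")
    np.savetxt(str(lab_path), ds.Y.toarray(), delimiter="\t", fmt="%d")


def normalize_rows(X: sp.spmatrix) -> sp.csr_matrix:
    """L2-normalize each nonzero row (zero rows pass through, with warning)."""
    X = sp.csr_matrix(X, dtype=np.float64, copy=True)
    norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=1)).ravel())
    zero = norms == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero row(s) left unnormalized")
    scale = np.where(zero, 1.0, norms)
    X = sp.diags(1.0 / scale) @ X
    return sp.csr_matrix(X)
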