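"""BM25 term weighting and L2 normalization of token-count corpora.

Documents arrive as a table of ``(doc_id, term, count)`` rows; they leave
as unit-length nonnegative vectors in term space.  The weighting is the
Okapi BM25 TF-IDF family: term-frequency saturation controlled by ``k1``,
document-length normalization controlled by ``b``, and an IDF floored at
zero so every weight is nonnegative (cosine similarities then live in
[0, 1], which the neighbor-graph weights rely on).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import normalize_rows


@dataclass(frozen=True)
class BM25Params:
    """Okapi BM25 constants: ``k1`` (saturation), ``b`` (length norm)."""

    k1: float = 1.2
    b: float = 0.75

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError("k1 must be > 0")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must be in [0, 1]")


def _idf(df: int, n_docs: int) -> float:
    # probabilistic idf, floored at 0 to keep weights nonnegative
    return max(0.0, math.log((n_docs - df + 0.5) / (df + 0.5)))


def bm25_weight(
    tf: float,
    df: int,
    n_docs: int,
    doc_len: float,
    avg_len: float,
    params: BM25Params = BM25Params(),
) -> float:
    """BM25 weight of one term in one document.

    ``idf(df, n_docs) * tf*(k1+1) / (tf + k1*(1 - b + b*doc_len/avg_len))``
    with the floored probabilistic idf.  Zero when ``tf`` is zero; saturates
    at ``idf*(k1+1)`` as ``tf`` grows.
    """
    if avg_len <= 0:
        raise ValueError("avg_len must be positive")
    if tf == 0:
        return 0.0
    if df < 1:
        raise ValueError("df must be >= 1 for a term present in a document")
    denom = tf + params.k1 * (1.0 - params.b + params.b * doc_len / avg_len)
    return _idf(df, n_docs) * tf * (params.k1 + 1.0) / denom


def vectorize_corpus(
    token_counts: pd.DataFrame, params: BM25Params = BM25Params()
) -> tuple[sp.csr_matrix, list, list[str]]:
    """BM25-weight and L2-normalize a token-count corpus.

    Parameters
    ----------
    token_counts
        DataFrame with columns ``doc_id``, ``term``, ``count``.  Document and
        term order follow first appearance.
    params
        BM25 constants.

    Returns
    -------
    X : csr_matrix
        n_docs x n_terms feature matrix; every nonzero row has unit norm.
    doc_ids : list
        Row order.
    vocabulary : list of str
        Column order.
    """
    required = {"doc_id", "term", "count"}
    if not required.issubset(token_counts.columns):
        raise ValueError(f"token_counts must have columns {sorted(required)}")
    tc = token_counts[token_counts["count"] > 0]
    if tc.empty:
        raise ValueError("corpus has no positive token counts")

    doc_ids = list(dict.fromkeys(tc["doc_id"]))
    vocab = list(dict.fromkeys(tc["term"]))
    doc_index = {d: i for i, d in enumerate(doc_ids)}
    term_index = {t: j for j, t in enumerate(vocab)}

    rows = tc["doc_id"].map(doc_index).to_numpy()
    cols = tc["term"].map(term_index).to_numpy()
    counts = tc["count"].to_numpy(dtype=np.float64)

    n_docs, n_terms = len(doc_ids), len(vocab)
    TF = sp.csr_matrix((counts, (rows, cols)), shape=(n_docs, n_terms))
    TF.sum_duplicates()

    doc_len = np.asarray(TF.sum(axis=1)).ravel()
    avg_len = float(doc_len.mean())
    df = np.asarray((TF > 0).sum(axis=0)).ravel()
    idf = np.maximum(0.0, np.log((n_docs - df + 0.5) / (df + 0.5)))

    W = TF.tocoo()
    tf = W.data
    denom = tf + params.k1 * (1.0 - params.b + params.b * doc_len[W.row] / avg_len)
    data = idf[W.col] * tf * (params.k1 + 1.0) / denom
    X = sp.csr_matrix((data, (W.row, W.col)), shape=TF.shape)
    X.eliminate_zeros()

    zero_rows = np.flatnonzero(np.asarray(X.getnnz(axis=1)) == 0)
    if zero_rows.size:
        warnings.warn(
            f"{zero_rows.size} document(s) have all-zero vectors after "
            "BM25 weighting (all their terms have floored idf)"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X = normalize_rows(X)
    return X, doc_ids, vocab
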