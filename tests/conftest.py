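import numpy as np
import pytest
import scipy.sparse as sp

from labelrestore import SyntheticSpec, generate


@pytest.fixture(scope="session")
def compact_dataset():
    """Well-separated synthetic multilabel data used across modules."""
    return generate(SyntheticSpec(n_docs=200, n_labels=6, n_features=30,
                                  spread=0.08, co_label_rate=0.5, seed=7))


def random_multilabel(rng, n, m, d=12, density=0.4):
    """Random dataset with >= 1 label per row (helper, not a fixture)."""
    X = sp.csr_matrix(np.abs(rng.standard_normal((n, d))))
    Y = (rng.random((n, m)) < density).astype(np.int8)
    empty = Y.sum(axis=1) == 0
    Y[empty, rng.integers(0, m, size=int(empty.sum()))] = 1
    return X, sp.csr_matrix(Y)
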