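"""SoftSL: KL/entropy primitives, the misalignment objective, and the
monotone minimizer."""

import numpy as np
import pytest
import scipy.sparse as sp

from labelrestore import (
    DeletionSpec,
    NeighborGraph,
    SoftSLParams,
    build_graph,
    delete_labels,
    entropy,
    kl_divergence,
    minimize,
    objective,
    restore_softsl,
)
from labelrestore.softsl import ProbabilityTable

from conftest import random_multilabel


def test_kl_identity_and_closed_form():
    p = np.array([0.3, 0.7])
    assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)
    # KL((1,0), (.5,.5)) -> log 2 as the floor vanishes
    val = kl_divergence([1.0, 0.0], [0.5, 0.5], eps=1e-300)
    assert val == pytest.approx(np.log(2), rel=1e-9)


def test_kl_nonnegative_gibbs():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        p = rng.dirichlet(np.ones(4))
        q = rng.dirichlet(np.ones(4))
        assert kl_divergence(p, q) >= -1e-12


def test_entropy_closed_forms():
    assert entropy([1.0, 0.0, 0.0]) == pytest.approx(0.0, abs=1e-8)
    assert entropy(np.full(5, 0.2)) == pytest.approx(np.log(5), rel=1e-12)
    assert entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5 * np.log(2), rel=1e-12)


def _table_from_Y(Y):
    return ProbabilityTable.from_labels(sp.csr_matrix(Y))


def test_reference_distributions_uniform_over_positives():
    pt = _table_from_Y(np.array([[1, 1, 0], [0, 0, 1]], dtype=np.int8))
    np.testing.assert_allclose(pt.r, [[0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])
    assert pt.labeled.all()


def test_objective_vanishes_at_reference():
    rng = np.random.default_rng(1)
    X, Y = random_multilabel(rng, 10, 3)
    g = build_graph(X, 3)
    pt = _table_from_Y(Y)
    params = SoftSLParams(k=3, mu=0.0, nu=0.0)
    assert objective(pt, g, params) == pytest.approx(0.0, abs=1e-6)


def test_objective_matches_term_by_term_hand_computation():
    """4-node instance evaluated independently term by term."""
    indices = np.array([[1], [0], [3], [2]])
    weights = np.array([[0.8], [0.8], [0.6], [0.6]])
    g = NeighborGraph(k=1, indices=indices, weights=weights)
    r = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0], [1.0, 0.0]])
    p = np.array([[0.7, 0.3], [0.4, 0.6], [0.2, 0.8], [0.6, 0.4]])
    pt = ProbabilityTable(p=p, r=r, labeled=np.ones(4, dtype=bool))
    params = SoftSLParams(k=1, mu=0.3, nu=0.2, eps=1e-10)
    expected = sum(kl_divergence(r[i], p[i]) for i in range(4))
    expected += 0.3 * sum(
        weights[i, 0] * kl_divergence(p[i], p[indices[i, 0]]) for i in range(4)
    )
    expected -= 0.2 * sum(entropy(p[i]) for i in range(4))
    assert objective(pt, g, params) == pytest.approx(expected, rel=1e-10)


def test_decoupled_problem_returns_reference():
    """mu = nu = 0: the minimizer is p = r with objective 0."""
    rng = np.random.default_rng(2)
    X, Y = random_multilabel(rng, 12, 4)
    g = build_graph(X, 3)
    res = minimize(_table_from_Y(Y), g, SoftSLParams(k=3, mu=0.0, nu=0.0))
    assert res.converged
    assert res.trace[-1] == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(res.table.p, res.table.r, atol=1e-6)


def test_duplicate_documents_get_identical_rows():
    Xd = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    Y = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=np.int8)
    g = build_graph(sp.csr_matrix(Xd), 2)
    res = minimize(_table_from_Y(Y), g, SoftSLParams(k=2, mu=1.0))
    np.testing.assert_allclose(res.table.p[0], res.table.p[1], atol=1e-8)
    np.testing.assert_allclose(res.table.p[2], res.table.p[3], atol=1e-8)


@pytest.mark.parametrize("seed", range(5))
def test_monotone_trace_and_row_stochastic(seed):
    rng = np.random.default_rng(seed)
    X, Y = random_multilabel(rng, 20, 4)
    g = build_graph(X, 4)
    res = minimize(_table_from_Y(Y), g,
                   SoftSLParams(k=4, mu=0.7, nu=0.05, max_iter=100))
    diffs = np.diff(res.trace)
    assert (diffs <= 1e-9).all()
    np.testing.assert_allclose(res.table.p.sum(axis=1), 1.0, atol=1e-8)
    assert (res.table.p >= 0).all()


def test_beats_random_tables(seed=3):
    """Final objective <= initialization and <= 100 random tables."""
    rng = np.random.default_rng(seed)
    X, Y = random_multilabel(rng, 20, 4)
    g = build_graph(X, 4)
    pt0 = _table_from_Y(Y)
    params = SoftSLParams(k=4, mu=0.7)
    res = minimize(pt0, g, params)
    final = objective(res.table, g, params)
    assert final <= objective(pt0, g, params) + 1e-12
    for _ in range(100):
        p = rng.dirichlet(np.ones(4), size=20)
        rand_pt = ProbabilityTable(p=p, r=pt0.r, labeled=pt0.labeled)
        assert final <= objective(rand_pt, g, params) + 1e-12


def test_larger_mu_pulls_neighbors_together():
    rng = np.random.default_rng(6)
    X, Y = random_multilabel(rng, 25, 3)
    g = build_graph(X, 4)
    pt0 = _table_from_Y(Y)

    def max_adjacent_kl(mu):
        res = minimize(pt0, g, SoftSLParams(k=4, mu=mu, max_iter=400, tol=1e-10))
        P = res.table.p
        return max(
            kl_divergence(P[i], P[j])
            for i in range(25) for j in g.indices[i]
        )

    assert max_adjacent_kl(50.0) < max_adjacent_kl(0.05)


def test_restore_thresholding_and_monotonicity():
    rng = np.random.default_rng(7)
    X, Y = random_multilabel(rng, 30, 4)
    params_hi = SoftSLParams(k=5, mu=0.5, T=0.5)
    params_lo = SoftSLParams(k=5, mu=0.5, T=0.005)
    hi = restore_softsl(X, Y, params_hi).pairs
    lo = restore_softsl(X, Y, params_lo).pairs
    assert hi <= lo
    Yd = Y.toarray()
    assert all(Yd[d, l] == 0 for d, l in lo)


def test_synthetic_deleted_label_recovered():
    """Two tight clusters, one label deleted; its probability exceeds the
    default T = 0.005 and the pair is proposed."""
    A, B = np.array([1.0, 0.05]), np.array([0.05, 1.0])
    X = sp.csr_matrix(np.vstack([A, A * 1.1, A + 0.02, B, B * 2, B + 0.01]))
    Y = np.array([[1, 0], [1, 0], [1, 0], [0, 1], [0, 1], [0, 1]], dtype=np.int8)
    Y[2] = [1, 0]
    Y_true = Y.copy()
    Y_true[2] = [1, 1]   # doc 2 also belongs to B; that label was deleted
    Xd = np.asarray(X.todense())
    Xd[2] = (A + B) / 2  # sits between the clusters
    pairs = restore_softsl(sp.csr_matrix(Xd), sp.csr_matrix(Y),
                           SoftSLParams(k=3, mu=1.0, T=0.005))
    assert (2, 1) in pairs


def test_invalid_params():
    with pytest.raises(ValueError):
        SoftSLParams(mu=-1)
    with pytest.raises(ValueError):
        SoftSLParams(T=1.5)
    with pytest.raises(ValueError):
        SoftSLParams(tol=0)
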