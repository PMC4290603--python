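"""Unit tests for the elementary model quantities: divergences, likelihood,
regularizers, initialization, clamping and the two M-step updates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smcc.model as md
from smcc.model import (
    LabelAffinity,
    ModelParams,
    RegularizerWeights,
    build_mstep_system,
    clamp_labeled,
    e_step,
    init_params,
    instance_similarity,
    label_affinity,
    label_regularizer,
    log_likelihood,
    m_step_pcx,
    m_step_pwc,
    network_regularizer,
    objective,
    predict_labels,
    symmetric_kl,
)
from conftest import random_dataset


# ---------------------------------------------------------------------------
# symmetric KL


def test_symmetric_kl_identical_is_zero():
    assert symmetric_kl([0.5, 0.5], [0.5, 0.5]) == 0.0


def test_symmetric_kl_hand_value():
    # 0.5*[0.8 ln4 + 0.2 ln(1/4) + 0.2 ln(1/4) + 0.8 ln4] = 0.6 ln 4
    got = symmetric_kl([0.8, 0.2], [0.2, 0.8])
    assert got == pytest.approx(0.6 * np.log(4.0), rel=1e-12)


def test_symmetric_kl_input_validation():
    with pytest.raises(ValueError):
        symmetric_kl([0.5, 0.5], [1.0])
    with pytest.raises(ValueError):
        symmetric_kl([np.nan, 1.0], [0.5, 0.5])
    with pytest.raises(ValueError):
        symmetric_kl([0.5, 0.5], [0.5, 0.5], eps=0.0)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
       st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
def test_symmetric_kl_symmetry_and_nonnegativity(p, q):
    n = min(len(p), len(q))
    p = np.array(p[:n]) / np.sum(p[:n])
    q = np.array(q[:n]) / np.sum(q[:n])
    d = symmetric_kl(p, q)
    assert d >= 0
    assert d == pytest.approx(symmetric_kl(q, p), abs=1e-12)


# ---------------------------------------------------------------------------
# likelihood and regularizers


def _single_class_dataset(counts_row):
    import scipy.sparse as sp
    from smcc.data import NetworkedDataset

    return NetworkedDataset(
        node_ids=["a"], adjacency=sp.csr_array((1, 1)),
        counts=np.array([counts_row], float),
        labels=np.array([[1]], dtype=np.int8),
        labeled_mask=np.array([True]), class_names=["c1"],
    )


def test_log_likelihood_single_component_closed_form():
    ds = _single_class_dataset([1.0, 1.0])
    params = ModelParams(np.array([[0.5], [0.5]]), np.array([[1.0]]))
    assert log_likelihood(ds, params) == pytest.approx(2 * np.log(0.5), rel=1e-12)


def test_log_likelihood_zero_counts_is_zero():
    ds = _single_class_dataset([0.0, 0.0])
    params = ModelParams(np.array([[0.5], [0.5]]), np.array([[1.0]]))
    assert log_likelihood(ds, params) == 0.0


def test_network_regularizer_identical_rows_zero(rng):
    ds = random_dataset(rng)
    pcx = np.full((ds.n_nodes, 3), 1 / 3)
    assert network_regularizer(pcx, ds.adjacency) == 0.0


def test_network_regularizer_empty_graph_zero():
    pcx = np.array([[0.9, 0.1], [0.1, 0.9]])
    import scipy.sparse as sp
    assert network_regularizer(pcx, sp.csr_array((2, 2))) == 0.0


def test_network_regularizer_single_edge_double_count():
    # one undirected edge counted in both orientations
    pcx = np.array([[0.8, 0.2], [0.2, 0.8]])
    adj = np.array([[0, 1], [1, 0]], float)
    expected = 2 * 0.6 * np.log(4.0)
    assert network_regularizer(pcx, adj) == pytest.approx(expected, rel=1e-9)


def test_label_affinity_parallel_disjoint_and_hand_value(rng):
    from smcc.data import NetworkedDataset
    import scipy.sparse as sp

    # columns over labeled nodes: Y1=[1,1,0], Y2=[1,0,1], Y3=[0,1,1]
    labels = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1]], dtype=np.int8)
    ds = NetworkedDataset(
        node_ids=["a", "b", "c"], adjacency=sp.csr_array((3, 3)),
        counts=np.ones((3, 2)), labels=labels,
        labeled_mask=np.array([True, True, True]), class_names=["c1", "c2", "c3"],
    )
    f = label_affinity(ds).f
    # Y1=[1,1,0], Y2=[1,0,1] -> dot 1 / (sqrt2*sqrt2) = 0.5
    assert f[0, 1] == pytest.approx(0.5)
    assert np.allclose(np.diag(f), 1.0)
    assert np.allclose(f, f.T)


def test_label_affinity_identical_and_disjoint_supports():
    from smcc.data import NetworkedDataset
    import scipy.sparse as sp

    labels = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=np.int8)
    ds = NetworkedDataset(
        node_ids=["a", "b", "c"], adjacency=sp.csr_array((3, 3)),
        counts=np.ones((3, 2)), labels=labels,
        labeled_mask=np.array([True, True, True]), class_names=["c1", "c2", "c3"],
    )
    f = label_affinity(ds).f
    assert f[0, 1] == pytest.approx(1.0)  # identical supports
    assert f[0, 2] == pytest.approx(0.0)  # disjoint supports


def test_label_regularizer_identical_columns_zero():
    pcx = np.tile([[0.5, 0.5]], (4, 1))
    aff = LabelAffinity(np.array([[1.0, 0.7], [0.7, 1.0]]))
    assert label_regularizer(pcx, aff) == pytest.approx(0.0, abs=1e-12)


def test_label_regularizer_diagonal_affinity_zero(rng):
    pcx = rng.dirichlet(np.ones(3), size=5)
    aff = LabelAffinity(np.eye(3))
    assert label_regularizer(pcx, aff) == pytest.approx(0.0, abs=1e-12)


def _label_reg_bruteforce(pcx, f, eps=1e-12):
    r = np.maximum(pcx, eps)
    k = r.shape[1]
    h = 0.0
    for a in range(k):
        for b in range(k):
            d = 0.0
            for i in range(r.shape[0]):
                d += r[i, a] * np.log(r[i, a] / r[i, b])
                d += r[i, b] * np.log(r[i, b] / r[i, a])
            h += 0.5 * d * f[a, b]
    return h


def test_label_regularizer_matches_bruteforce(rng):
    pcx = rng.dirichlet(np.ones(4), size=6)
    raw = rng.random((4, 4))
    f = np.clip((raw + raw.T) / 2, 0, 1)
    np.fill_diagonal(f, 1.0)
    aff = LabelAffinity(f)
    assert label_regularizer(pcx, aff) == pytest.approx(_label_reg_bruteforce(pcx, f), rel=1e-9)


def test_objective_decomposition_and_plsa_limit(rng):
    ds = random_dataset(rng)
    params = init_params(ds)
    aff = label_affinity(ds)
    o0 = objective(ds, params, ds.adjacency, aff, RegularizerWeights(0.0, 0.0))
    assert o0.objective == o0.loglik  # pure pLSA limit
    o1 = objective(ds, params, ds.adjacency, aff, RegularizerWeights(1.0, 0.5))
    o2 = objective(ds, params, ds.adjacency, aff, RegularizerWeights(2.0, 0.5))
    if o1.network_pen > 0:
        assert o2.objective < o1.objective  # doubling alpha strictly decreases O
    # naive recomputation of the composite
    assert o1.objective == pytest.approx(
        o1.loglik - 1.0 * o1.network_pen - 0.5 * o1.label_pen, rel=1e-12
    )
    assert o1.network_pen == pytest.approx(network_regularizer(params, ds.adjacency), rel=1e-12)
    assert o1.label_pen == pytest.approx(label_regularizer(params, aff), rel=1e-12)


# ---------------------------------------------------------------------------
# clamping and initialization


def test_clamp_uniform_over_known_labels():
    from smcc.data import NetworkedDataset
    import scipy.sparse as sp

    labels = np.array([[1, 0, 1, 0], [0, 0, 0, 0]], dtype=np.int8)
    ds = NetworkedDataset(
        node_ids=["a", "b"], adjacency=sp.csr_array((2, 2)), counts=np.ones((2, 2)),
        labels=labels, labeled_mask=np.array([True, False]), class_names=list("wxyz"),
    )
    pcx = np.full((2, 4), 0.25)
    out = clamp_labeled(pcx, ds)
    assert out[0].tolist() == [0.5, 0.0, 0.5, 0.0]
    assert out[1].tolist() == [0.25] * 4  # unlabeled untouched
    assert np.array_equal(clamp_labeled(out, ds), out)  # idempotent


def test_init_params_prior_rows_and_smoothing():
    from smcc.data import NetworkedDataset
    import scipy.sparse as sp

    # 4 labeled single-label nodes: 3x class A, 1x class B; 1 unlabeled
    labels = np.array([[1, 0], [1, 0], [1, 0], [0, 1], [0, 0]], dtype=np.int8)
    ds = NetworkedDataset(
        node_ids=list("abcde"), adjacency=sp.csr_array((5, 5)),
        counts=np.ones((5, 2)), labels=labels,
        labeled_mask=np.array([True, True, True, True, False]), class_names=["A", "B"],
    )
    params = init_params(ds)
    assert params.p_c_given_x[4].tolist() == pytest.approx([0.75, 0.25])
    assert params.p_c_given_x[0].tolist() == [1.0, 0.0]  # clamped


def test_init_params_pwc_smoothed_column():
    ds = _single_class_dataset([2.0, 0.0])
    s = 0.5  # default smoothing 1/M with M=2
    params = init_params(ds)
    assert params.p_w_given_c[:, 0] == pytest.approx([(2 + s) / (2 + 2 * s), s / (2 + 2 * s)])


def test_init_params_satisfies_invariants(rng):
    params = init_params(random_dataset(rng, n=7, m=5, k=4, n_labeled=3))
    assert np.allclose(params.p_w_given_c.sum(axis=0), 1.0, atol=1e-9)
    assert np.allclose(params.p_c_given_x.sum(axis=1), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# E-step and M-steps


def test_e_step_single_component_posterior_is_one():
    ds = _single_class_dataset([1.0, 2.0])
    post = e_step(ds, init_params(ds))
    assert post.at(0, 0) == pytest.approx([1.0])


def test_e_step_bayes_ratio():
    ds = _single_class_dataset([1.0, 1.0])
    post = md.Posterior(
        np.array([[1.0]]),
        pwc=np.array([[0.5, 0.25]]),
        pcx=np.array([[0.4, 0.6]]),
    )
    assert post.at(0, 0) == pytest.approx([0.2 / 0.35, 0.15 / 0.35])


def test_e_step_posterior_normalized_at_cells(rng):
    ds = random_dataset(rng)
    post = e_step(ds, init_params(ds))
    nz = np.argwhere(ds.counts > 0)
    for i, j in nz[:10]:
        assert post.at(i, j).sum() == pytest.approx(1.0, abs=1e-12)


def test_m_step_pwc_single_class_gives_global_frequencies(rng):
    ds = random_dataset(rng, k=3)
    # K=1 collapse: force a single-class posterior via K=1 params
    counts = ds.counts
    post = md.Posterior(counts, np.full((ds.n_features, 1), 1 / ds.n_features),
                        np.ones((ds.n_nodes, 1)))
    pwc = md.m_step_pwc(ds, post)
    expected = counts.sum(axis=0) / counts.sum()
    assert pwc[:, 0] == pytest.approx(expected, rel=1e-12)


def test_m_step_pwc_one_hot_posterior_per_class_frequencies():
    ds = _single_class_dataset([1.0, 0.0])
    counts = np.array([[1.0, 0.0], [0.0, 1.0]])
    # one-hot class assignment: node 0 -> class 1, node 1 -> class 2
    post = md.Posterior(counts, pwc=np.array([[1.0, 0.0], [0.0, 1.0]]),
                        pcx=np.array([[1.0, 0.0], [0.0, 1.0]]))
    pwc = md.m_step_pwc(type("D", (), {"counts": counts, "n_features": 2})(), post)
    assert np.allclose(pwc, [[1.0, 0.0], [0.0, 1.0]])


def test_m_step_pwc_column_stochastic(rng):
    ds = random_dataset(rng, n=6, m=5, k=3)
    post = e_step(ds, init_params(ds))
    pwc = m_step_pwc(ds, post)
    assert np.allclose(pwc.sum(axis=0), 1.0, atol=1e-9)
    assert (pwc >= 0).all()


def test_m_step_pcx_unregularized_is_plsa_update(rng):
    ds = random_dataset(rng, n=6, m=5, k=3)
    params = init_params(ds)
    post = e_step(ds, params)
    aff = label_affinity(ds)
    out = m_step_pcx(ds, post, ds.adjacency, aff, RegularizerWeights(0.0, 0.0),
                     prev_pcx=params.p_c_given_x)
    z = post.node_class_totals()
    expected = clamp_labeled(z / z.sum(axis=1, keepdims=True), ds)
    assert np.allclose(out, expected, atol=1e-9)


def test_m_step_pcx_single_class_rows_are_one():
    ds = _single_class_dataset([1.0, 1.0])
    params = init_params(ds)
    post = e_step(ds, params)
    out = m_step_pcx(ds, post, ds.adjacency, label_affinity(ds),
                     RegularizerWeights(1.0, 1.0), prev_pcx=params.p_c_given_x)
    assert np.allclose(out, 1.0)


def test_mstep_system_rho_identity_and_psd(rng):
    ds = random_dataset(rng, n=8, m=6, k=4, n_labeled=3)
    post = e_step(ds, init_params(ds))
    system = build_mstep_system(ds, post, ds.adjacency, label_affinity(ds),
                                RegularizerWeights(1.0, 1.0))
    row_counts = ds.counts.sum(axis=1)
    assert np.allclose(system.omega_diag, np.tile(row_counts, ds.n_classes))
    for _ in range(20):
        v = rng.standard_normal(ds.n_nodes * ds.n_classes)
        assert v @ (system.graph_operator @ v) >= -1e-10
        assert v @ (system.label_operator @ v) >= -1e-10


# ---------------------------------------------------------------------------
# prediction helpers


def test_predict_labels_gap_rule_top_one():
    table = predict_labels(np.array([[0.5, 0.3, 0.15, 0.05]]))
    assert table.relevant_sets[0] == ["c1"]


def test_predict_labels_gap_rule_top_three():
    table = predict_labels(np.array([[0.4, 0.35, 0.2, 0.05]]))
    assert table.relevant_sets[0] == ["c1", "c2", "c3"]


def test_predict_labels_one_hot_and_all_equal():
    table = predict_labels(np.array([[0.0, 1.0, 0.0], [1 / 3, 1 / 3, 1 / 3]]))
    assert table.relevant_sets[0] == ["c2"]
    assert table.relevant_sets[1] == ["c1"]  # stable fallback


def test_predict_labels_single_class():
    table = predict_labels(np.array([[1.0]]))
    assert table.relevant_sets[0] == ["c1"]


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 10_000))
def test_predict_labels_relevant_sets_nonempty_and_contain_top(seed):
    r = np.random.default_rng(seed)
    scores = r.dirichlet(np.ones(5), size=4)
    table = predict_labels(scores)
    for row, rel in zip(scores, table.relevant_sets):
        assert rel
        top = f"c{int(row.argmax()) + 1}"
        assert top in rel


def test_instance_similarity_values():
    scores = np.array([[0.8, 0.2], [0.2, 0.8], [0.8, 0.2], [1.0, 0.0], [0.0, 1.0]])
    assert instance_similarity(scores, 0, 2) == pytest.approx(1.0)
    assert instance_similarity(scores, 3, 4) == pytest.approx(0.0)
    assert instance_similarity(scores, 0, 1) == pytest.approx(0.32 / 0.68, rel=1e-9)
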