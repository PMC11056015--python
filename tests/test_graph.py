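import numpy as np
import pytest

from spatialcomm.exceptions import ValidationError
from spatialcomm.graph import (
    aggregate_pair_weights,
    attenuate_paths,
    build_communication_graph,
    cluster_coefficient_matrix,
    export_graph,
    threshold_by_mean,
)
from spatialcomm.io import read_matrix_tsv


def brute_force_attenuated(w, mean):
    """Independent recursive simple-path enumerator."""
    a = w.shape[0]
    out = np.zeros((a, a))

    def walk(path):
        src = path[0]
        last = path[-1]
        if len(path) > 1:
            contrib = sum(
                w[i, j] - mean * 10.0 ** (1 - s)
                for s, (i, j) in enumerate(zip(path[:-1], path[1:]), start=1)
            )
            out[src, last] += contrib
        for nxt in range(a):
            if nxt not in path and w[last, nxt] != 0:
                walk(path + [nxt])

    for src in range(a):
        walk([src])
    return out


def test_cluster_coefficient_matrix_means():
    coef = np.array([[1.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
    assignments = np.array([0, 0, 1])
    m = cluster_coefficient_matrix(coef, assignments)
    np.testing.assert_allclose(m, [[2.0, 0.0], [0.0, 4.0]])


def test_cluster_matrix_hand_fixture():
    # 4 genes, 2 types, 2 clusters
    coef = np.array([[2.0, 1.0], [4.0, 3.0], [0.0, 5.0], [0.0, 7.0]])
    m = cluster_coefficient_matrix(coef, np.array([0, 0, 1, 1]))
    np.testing.assert_allclose(m, [[3.0, 2.0], [0.0, 6.0]])


def test_single_gene_cluster_verbatim():
    coef = np.array([[1.5, -2.5]])
    m = cluster_coefficient_matrix(coef, np.array([0]))
    np.testing.assert_allclose(m, coef)


def test_aggregate_345():
    # receiver "r": two kept clusters with coefficients 3 and 4 toward sender 0
    mats = {"r": np.array([[3.0, 0.0], [4.0, 0.0]]), "s": np.zeros((2, 2))}
    w, k = aggregate_pair_weights(mats, ["s", "r"], k_min=2)
    assert k == 2
    assert w[0, 1] == pytest.approx(5.0)  # sender index 0 -> receiver index 1
    assert np.all(w[:, 0] == 0)


def test_aggregate_keeps_largest_norm_clusters():
    mats = {
        "r": np.array([[3.0, 4.0], [2.0, 0.0], [1.0, 0.0]]),  # norms 5, 2, 1
        "s": np.array([[0.0, 0.0], [0.0, 0.0]]),
    }
    w, k = aggregate_pair_weights(mats, ["s", "r"], k_min=2)
    assert k == 2
    # clusters with norm 5 and 2 kept: sqrt(3^2 + 2^2), sqrt(4^2)
    assert w[0, 1] == pytest.approx(np.sqrt(13))
    assert w[1, 1] == pytest.approx(4.0)


def test_aggregate_kmin_too_large():
    mats = {"r": np.ones((2, 2)), "s": np.ones((3, 2))}
    with pytest.raises(ValidationError):
        aggregate_pair_weights(mats, ["r", "s"], k_min=3)


def test_threshold_by_mean_hand():
    w = np.array([[0.0, 2.0], [4.0, 0.0]])
    out, mean = threshold_by_mean(w)
    assert mean == pytest.approx(3.0)
    np.testing.assert_allclose(out, [[0.0, 0.0], [4.0, 0.0]])


def test_threshold_equal_entries_all_kept():
    w = np.full((3, 3), 2.0)
    out, mean = threshold_by_mean(w)
    assert mean == pytest.approx(2.0)
    off = ~np.eye(3, dtype=bool)
    assert np.all(out[off] == 2.0)
    assert np.all(np.diag(out) == 0)


def test_threshold_all_zero():
    out, mean = threshold_by_mean(np.zeros((2, 2)))
    assert mean == 0.0
    assert np.all(out == 0)


def test_attenuation_hand_oracle():
    """3-node worked example: direct (5-2) plus two-edge (4-2)+(6-0.2)."""
    w = np.zeros((3, 3))
    w[0, 1], w[0, 2], w[2, 1] = 5.0, 4.0, 6.0
    r = attenuate_paths(w, 2.0)
    assert r[0, 1] == pytest.approx(10.8)
    assert r[0, 2] == pytest.approx(2.0)  # single edge 4 - 2
    assert r[1, 0] == 0.0  # no path


def test_attenuation_edge_at_mean_contributes_zero():
    w = np.zeros((2, 2))
    w[0, 1] = 3.0
    assert attenuate_paths(w, 3.0)[0, 1] == pytest.approx(0.0)


def test_attenuation_matches_brute_force_random_graphs():
    rng = np.random.default_rng(0)
    for _ in range(15):
        a = rng.integers(2, 7)
        w = rng.uniform(0, 5, size=(a, a))
        w[rng.random((a, a)) < 0.4] = 0.0
        np.fill_diagonal(w, 0.0)
        thresholded, mean = threshold_by_mean(w)
        ours = attenuate_paths(thresholded, mean)
        theirs = brute_force_attenuated(thresholded, mean)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


def test_attenuated_nonnegative_after_threshold():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a = rng.integers(3, 9)
        w = rng.uniform(0, 3, size=(a, a))
        np.fill_diagonal(w, 0.0)
        thresholded, mean = threshold_by_mean(w)
        r = attenuate_paths(thresholded, mean)
        assert np.all(r >= -1e-12)


def test_attenuation_requires_zero_diagonal():
    with pytest.raises(ValidationError):
        attenuate_paths(np.eye(3), 0.5)


def test_build_and_export(tmp_path):
    mats = {
        "A": np.array([[0.0, 3.0, 1.0], [0.0, 0.0, 4.0]]),
        "B": np.array([[5.0, 0.0, 0.0], [1.0, 0.0, 2.0]]),
        "C": np.array([[2.0, 2.0, 0.0], [0.0, 3.0, 0.0]]),
    }
    g = build_communication_graph(mats, ["A", "B", "C"])
    assert g.k_min_clusters == 2
    files = export_graph(g, tmp_path)
    # matrix TSV round trip
    back = read_matrix_tsv(files["attenuated_matrix"])
    np.testing.assert_allclose(back.to_numpy(), g.attenuated, atol=1e-5)
    # edge list row count matches nonzero entries
    n_edges = np.count_nonzero(g.thresholded)
    lines = files["thresholded_edges"].read_text().splitlines()
    assert len(lines) == n_edges + 1
    # graphml round trip preserves weights
    import networkx as nx
    gml = nx.read_graphml(files["thresholded_graphml"])
    for s, t, data in gml.edges(data=True):
        i, j = list(g.type_order).index(s), list(g.type_order).index(t)
        assert data["weight"] == pytest.approx(g.thresholded[i, j], abs=1e-6)
    # dot file contains one line per edge
    dot = files["thresholded_dot"].read_text()
    assert dot.count("->") == n_edges


def test_export_empty_graph(tmp_path):
    mats = {"A": np.zeros((2, 2)), "B": np.zeros((2, 2))}
    g = build_communication_graph(mats, ["A", "B"])
    files = export_graph(g, tmp_path)
    assert files["thresholded_edges"].read_text() == "source,target,weight\n"
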