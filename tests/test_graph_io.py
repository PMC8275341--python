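"""Graph and feature I/O: canonicalization, validation, round-trips."""

import numpy as np
import pandas as pd
import pytest

from lupilink import (FeatureMatrix, HeteroGraph, canonical_edge,
                      feature_sparsity_histogram, read_features, read_graph,
                      write_features, write_graph)
from lupilink.graph import RELATIONS, GraphValidationError

from conftest import random_hetero_graph


def _write_tables(tmp_path, node_rows, edge_rows):
    nodes = tmp_path / "nodes.tsv"
    edges = tmp_path / "edges.tsv"
    pd.DataFrame(node_rows, columns=["node_id", "node_type"]).to_csv(
        nodes, sep="\t", index=False)
    pd.DataFrame(edge_rows, columns=["u", "v", "relation"]).to_csv(
        edges, sep="\t", index=False)
    return nodes, edges


NODES = [("d1", "disease"), ("d2", "disease"), ("g1", "gene"),
         ("g2", "gene"), ("g5", "gene")]


def test_reversed_duplicate_edges_collapse_to_one_canonical_edge(tmp_path):
    nodes, edges = _write_tables(tmp_path, NODES, [
        ("g5", "d2", "gene-disease"), ("d2", "g5", "gene-disease")])
    g = read_graph(nodes, edges)
    assert g.edges["gene-disease"] == {("d2", "g5")}
    assert g.has_edge("g5", "d2", "gene-disease")
    assert g.has_edge("d2", "g5", "gene-disease")


def test_per_relation_degrees_count_stored_neighbors(tmp_path):
    nodes, edges = _write_tables(
        tmp_path,
        [("d1", "disease"), ("g1", "gene"), ("g2", "gene")],
        [("g1", "g2", "gene-gene"), ("g1", "d1", "gene-disease")])
    g = read_graph(nodes, edges)
    assert g.degree("g1", "gene-gene") == 1
    assert g.degree("g2", "gene-gene") == 1
    assert g.degree("d1", "gene-gene") == 0
    assert g.degree("g1", "gene-disease") == 1


@pytest.mark.parametrize("bad_rows, message", [
    ([("g1", "g1", "gene-gene")], "self-loop"),
    ([("g1", "g2", "gene-disease")], "types"),
    ([("g1", "gX", "gene-gene")], "unknown node id"),
    ([("g1", "g2", "likes")], "unknown relation"),
])
def test_invalid_edges_are_rejected_with_informative_errors(tmp_path, bad_rows, message):
    nodes, edges = _write_tables(tmp_path, NODES, bad_rows)
    with pytest.raises(GraphValidationError, match=message):
        read_graph(nodes, edges)


def test_graph_round_trip_preserves_nodes_and_canonical_edges(tmp_path):
    g = random_hetero_graph(np.random.default_rng(3))
    write_graph(g, tmp_path / "n.tsv", tmp_path / "e.tsv")
    g2 = read_graph(tmp_path / "n.tsv", tmp_path / "e.tsv")
    assert g2.node_ids == g.node_ids
    assert g2.node_types == g.node_types
    assert g2.edges == g.edges


def test_edge_row_order_does_not_change_the_canonical_edge_set(tmp_path):
    rows = [("g1", "d1", "gene-disease"), ("g2", "g1", "gene-gene"),
            ("d2", "d1", "disease-disease")]
    nodes, edges = _write_tables(tmp_path, NODES, rows)
    g_fwd = read_graph(nodes, edges)
    nodes, edges = _write_tables(tmp_path, NODES, rows[::-1])
    g_rev = read_graph(nodes, edges)
    assert g_fwd.edges == g_rev.edges


def test_degree_sum_equals_twice_edge_count():
    g = random_hetero_graph(np.random.default_rng(8))
    for rel in RELATIONS:
        assert g.degree_vector(rel).sum() == 2 * g.num_edges(rel)


def test_dense_feature_file_round_trips_aligned_to_node_order(tmp_path):
    order = ["a", "b"]
    fm = FeatureMatrix(np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]),
                       np.ones((2, 3), dtype=np.int8))
    write_features(fm, order, tmp_path / "f.tsv")
    back = read_features(tmp_path / "f.tsv", order)
    np.testing.assert_allclose(back.values, fm.values)
    assert back.mask.all()


def test_missing_feature_rows_become_all_zero_with_zero_mask(tmp_path):
    pd.DataFrame([[0.5, 1.5]], index=pd.Index(["g1"], name="node_id"),
                 columns=["f0", "f1"]).to_csv(tmp_path / "f.tsv", sep="\t")
    fm = read_features(tmp_path / "f.tsv", ["g1", "g2"])
    np.testing.assert_allclose(fm.values[1], 0.0)
    assert not fm.mask[1].any()
    assert fm.mask[0].all()


def test_matrix_market_features_with_row_sidecar(tmp_path):
    import scipy.io
    import scipy.sparse as sp

    mat = sp.coo_matrix(np.array([[0.0, 2.5], [1.0, 0.0]]))
    scipy.io.mmwrite(str(tmp_path / "f.mtx"), mat)
    (tmp_path / "rows.txt").write_text("g2\ng1\n")
    fm = read_features(tmp_path / "f.mtx", ["g1", "g2", "g3"],
                       row_id_path=tmp_path / "rows.txt")
    np.testing.assert_allclose(fm.values[0], [1.0, 0.0])   # g1
    np.testing.assert_allclose(fm.values[1], [0.0, 2.5])   # g2
    assert not fm.mask[2].any()                             # g3 absent


def test_unknown_feature_row_id_raises(tmp_path):
    pd.DataFrame([[1.0]], index=pd.Index(["zz"], name="node_id"),
                 columns=["f0"]).to_csv(tmp_path / "f.tsv", sep="\t")
    with pytest.raises(GraphValidationError, match="zz"):
        read_features(tmp_path / "f.tsv", ["g1"])


def test_non_finite_feature_values_raise(tmp_path):
    pd.DataFrame([[np.inf]], index=pd.Index(["g1"], name="node_id"),
                 columns=["f0"]).to_csv(tmp_path / "f.tsv", sep="\t")
    with pytest.raises(GraphValidationError, match="non-finite"):
        read_features(tmp_path / "f.tsv", ["g1"])


@pytest.mark.parametrize("row, expected", [
    (np.zeros(10), 0.0),
    (np.ones(10), 1.0),
    (np.array([1.0, 2.0, 3.0] + [0.0] * 7), 0.3),
])
def test_sparsity_histogram_reports_nonzero_fractions(row, expected):
    fm = FeatureMatrix(row[None, :], (row != 0).astype(np.int8)[None, :])
    table = feature_sparsity_histogram(fm, ["n1"])
    assert table.loc[0, "nonzero_fraction"] == pytest.approx(expected)


def test_single_nonzero_of_twenty_dims_is_five_percent():
    vals = np.zeros((1, 20))
    vals[0, 7] = 2.5
    fm = FeatureMatrix(vals, (vals != 0).astype(np.int8))
    assert fm.nonzero_fraction()[0] == pytest.approx(0.05)


def test_masked_entries_must_hold_exact_zero():
    with pytest.raises(GraphValidationError):
        FeatureMatrix(np.array([[1.0]]), np.array([[0]]))
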