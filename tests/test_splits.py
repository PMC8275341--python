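"""Split regimes, leakage checking and feature masking."""

import numpy as np
import pytest

from lupilink import (SynthConfig, generate, leakage_check, make_split,
                      mask_features)
from lupilink.graph import canonical_edge
from lupilink.splits import SplitError, SplitSpec


@pytest.fixture(scope="module")
def bench():
    graph, feats, _ = generate(SynthConfig(seed=11))
    return graph, feats


def test_general_split_is_80_10_10(bench):
    graph, _ = bench
    spec = make_split(graph, "general", fold=0, seed=0)
    n = graph.num_edges("gene-disease")
    assert len(spec.test) == pytest.approx(n / 10, abs=1)
    assert len(spec.val) == pytest.approx(n / 10, abs=1)
    assert len(spec.train) == n - len(spec.test) - len(spec.val)
    assert leakage_check(spec, graph).passed


def test_ten_edges_split_into_8_1_1():
    genes = [f"g{i}" for i in range(10)]
    edges = {("d0", g) for g in genes}
    from lupilink import HeteroGraph
    # d1 has no associations, so non-edges exist for negative sampling
    g = HeteroGraph(["d0", "d1"] + genes, ["disease"] * 2 + ["gene"] * 10,
                    {"gene-disease": {canonical_edge(*e) for e in edges}})
    spec = make_split(g, "general", fold=0, seed=0)
    assert (len(spec.train), len(spec.val), len(spec.test)) == (8, 1, 1)


def test_ten_folds_partition_the_association_set(bench):
    graph, _ = bench
    all_edges = set(graph.edges["gene-disease"])
    seen = []
    for fold in range(10):
        spec = make_split(graph, "general", fold=fold, seed=4)
        seen.append(spec.test)
        assert spec.train | spec.val | spec.test == all_edges
    union = set().union(*seen)
    assert union == all_edges
    assert sum(len(t) for t in seen) == len(all_edges)  # pairwise disjoint


def test_new_disease_regime_blinds_test_diseases(bench):
    graph, _ = bench
    spec = make_split(graph, "new_disease", seed=1)
    test_diseases = {x for e in spec.test for x in e
                     if graph.type_of(x) == "disease"}
    for e in spec.train | spec.val:
        for x in e:
            if graph.type_of(x) == "disease":
                assert x not in test_diseases
    assert leakage_check(spec, graph).passed


def test_new_association_regime_blinds_both_endpoints(bench):
    graph, _ = bench
    spec = make_split(graph, "new_association", seed=1)
    test_nodes = {x for e in spec.test for x in e}
    for e in spec.train | spec.val:
        assert not (set(e) & test_nodes)
    assert leakage_check(spec, graph).passed


def test_singleton_regime_holds_out_each_single_association(bench):
    graph, _ = bench
    spec = make_split(graph, "singleton", seed=1)
    assert spec.test
    for e in spec.test:
        gene = e[0] if graph.type_of(e[0]) == "gene" else e[1]
        assert graph.degree(gene, "gene-disease") == 1
    assert leakage_check(spec, graph).passed


def test_singleton_regime_without_degree_one_genes_errors():
    from lupilink import HeteroGraph
    g = HeteroGraph(["d0", "d1", "g0"], ["disease", "disease", "gene"],
                    {"gene-disease": {("d0", "g0"), ("d1", "g0")}})
    with pytest.raises(SplitError, match="singleton"):
        make_split(g, "singleton", seed=0)


def test_unknown_regime_rejected(bench):
    with pytest.raises(SplitError, match="regime"):
        make_split(bench[0], "zero_shot", seed=0)


def test_leakage_check_flags_an_edge_in_both_train_and_test(bench):
    graph, _ = bench
    spec = make_split(graph, "general", fold=0, seed=2)
    edge = next(iter(spec.test))
    corrupted = SplitSpec(regime="general", train=spec.train | {edge[::-1]},
                          val=spec.val, test=spec.test)
    report = leakage_check(corrupted, graph)
    assert not report.passed
    assert any("train" in p and "test" in p for p in report.problems)


def test_leakage_check_flags_a_test_disease_with_training_edges(bench):
    graph, _ = bench
    spec = make_split(graph, "new_disease", seed=3)
    moved = next(iter(spec.test))
    corrupted = SplitSpec(regime="new_disease", train=spec.train | {moved},
                          val=spec.val, test=spec.test - {moved})
    assert not leakage_check(corrupted, graph).passed


def test_reversed_orientation_cannot_reach_a_different_partition(bench):
    graph, _ = bench
    spec = make_split(graph, "general", fold=0, seed=5)
    for e in spec.test:
        assert canonical_edge(*e[::-1]) not in spec.train
    assert leakage_check(spec, graph).passed


def test_split_round_trips_through_tsv(bench, tmp_path):
    from lupilink import read_split, write_split
    graph, _ = bench
    spec = make_split(graph, "general", fold=3, seed=9)
    write_split(spec, tmp_path / "split.tsv")
    back = read_split(tmp_path / "split.tsv")
    assert (back.train, back.val, back.test) == (spec.train, spec.val, spec.test)
    assert back.test_negatives == spec.test_negatives
    assert back.fold_id == 3 and back.regime == "general"


# -- feature masking ----------------------------------------------------------

def test_masking_keep_100_percent_is_identity(bench):
    _, feats = bench
    out = mask_features(feats.public, 100.0, {"g001"},
                        bench[0].node_ids, seed=0)
    np.testing.assert_array_equal(out.values, feats.public.values)


def test_masking_keep_0_percent_zeroes_the_scope(bench):
    graph, feats = bench
    out = mask_features(feats.public, 0.0, {"g001"}, graph.node_ids, seed=0)
    i = graph.index["g001"]
    np.testing.assert_array_equal(out.values[i], 0.0)
    assert not out.mask[i].any()


def test_masking_keeps_exactly_half_of_ten_dims():
    from lupilink import FeatureMatrix
    vals = np.arange(1.0, 11.0)[None, :].repeat(3, axis=0)
    fm = FeatureMatrix(vals, np.ones_like(vals, dtype=np.int8))
    out = mask_features(fm, 50.0, {"n0", "n2"}, ["n0", "n1", "n2"], seed=1)
    assert (out.values[0] != 0).sum() == 5
    np.testing.assert_array_equal(out.values[1], vals[1])
    assert (out.values[2] != 0).sum() == 5


def test_masking_with_empty_scope_is_identity(bench):
    graph, feats = bench
    out = mask_features(feats.public, 10.0, set(), graph.node_ids, seed=0)
    np.testing.assert_array_equal(out.values, feats.public.values)


def test_masking_is_seed_deterministic(bench):
    graph, feats = bench
    scope = set(graph.nodes_of_type("gene")[:20])
    a = mask_features(feats.public, 30.0, scope, graph.node_ids, seed=7)
    b = mask_features(feats.public, 30.0, scope, graph.node_ids, seed=7)
    np.testing.assert_array_equal(a.values, b.values)
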