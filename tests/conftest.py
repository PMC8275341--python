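"""Shared fixtures: hand-built toy graphs and generated benchmark bundles."""

from __future__ import annotations

import numpy as np
import pytest

from lupilink import (FeatureMatrix, HeteroGraph, NodeFeatures, SynthConfig,
                      generate)
from lupilink.graph import RELATIONS, canonical_edge


@pytest.fixture
def toy_graph() -> HeteroGraph:
    """Six nodes, all three relations, small enough to verify by hand."""
    return HeteroGraph(
        node_ids=["d1", "d2", "g1", "g2", "g3", "g4"],
        node_types=["disease", "disease", "gene", "gene", "gene", "gene"],
        edges={
            "gene-gene": {("g1", "g2"), ("g2", "g3")},
            "disease-disease": {("d1", "d2")},
            "gene-disease": {("d1", "g1"), ("d2", "g3"), ("d1", "g4")},
        },
    )


@pytest.fixture
def toy_features(toy_graph) -> NodeFeatures:
    rng = np.random.default_rng(5)
    pub = rng.standard_normal((toy_graph.n_nodes, 5))
    priv = rng.standard_normal((toy_graph.n_nodes, 4))
    ones = np.ones_like(pub, dtype=np.int8)
    return NodeFeatures(
        public=FeatureMatrix(pub, ones),
        privileged=FeatureMatrix(priv, np.ones_like(priv, dtype=np.int8)),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """The desk-scale benchmark graph (200 genes, 60 diseases, latent dim 8)."""
    return generate(SynthConfig(seed=11))


def random_hetero_graph(rng: np.random.Generator, max_nodes: int = 20,
                        edge_prob: float = 0.3) -> HeteroGraph:
    """A random typed graph for oracle-equivalence and property tests."""
    n_genes = int(rng.integers(2, max(3, max_nodes // 2)))
    n_diseases = int(rng.integers(1, max(2, max_nodes - n_genes)))
    genes = [f"g{i:02d}" for i in range(n_genes)]
    diseases = [f"d{i:02d}" for i in range(n_diseases)]
    edges = {rel: set() for rel in RELATIONS}
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_prob:
                edges["gene-gene"].add(canonical_edge(genes[i], genes[j]))
    for i in range(n_diseases):
        for j in range(i + 1, n_diseases):
            if rng.random() < edge_prob:
                edges["disease-disease"].add(canonical_edge(diseases[i], diseases[j]))
    for g in genes:
        for d in diseases:
            if rng.random() < edge_prob:
                edges["gene-disease"].add(canonical_edge(g, d))
    return HeteroGraph(diseases + genes,
                       ["disease"] * n_diseases + ["gene"] * n_genes, edges)
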