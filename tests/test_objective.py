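"""VGAE objective: KL closed form, negative sampling, reconstruction, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lupilink import (HeteroGraph, RgcnConfig, SplitSpec, TrainConfig, kl_term,
                      sample_negatives, train)
from lupilink.graph import canonical_edge
from lupilink.objective import (Adam, _pair_indices, loss_and_grad,
                                reconstruction_term)
from lupilink.rgcn import init_weights, normalized_adjacency

from conftest import random_hetero_graph


# -- KL -----------------------------------------------------------------------

@pytest.mark.parametrize("mu, var, expected", [
    (np.zeros((2, 3)), np.ones((2, 3)), 0.0),
    (np.array([[1.0]]), np.array([[1.0]]), 0.5),
    (np.array([[0.0]]), np.array([[0.25]]), 0.5 * (0.25 - 1 - np.log(0.25))),
])
def test_kl_closed_form_matches_hand_values(mu, var, expected):
    assert kl_term(mu, var) == pytest.approx(expected, abs=1e-12)


def test_kl_against_prior_with_quarter_variance_is_0_3181():
    assert kl_term(np.array([[0.0]]), np.array([[0.25]])) == \
        pytest.approx(0.3181, abs=5e-5)


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 10 ** 6))
def test_kl_is_nonnegative_for_random_posteriors(seed):
    rng = np.random.default_rng(seed)
    mu = rng.normal(scale=3.0, size=(4, 5))
    var = rng.uniform(0.01, 9.0, size=(4, 5))
    assert kl_term(mu, var) >= 0.0


def test_kl_rejects_nonpositive_variance():
    with pytest.raises(ValueError, match="positive"):
        kl_term(np.zeros((1, 1)), np.zeros((1, 1)))


def test_kl_is_invariant_to_node_ordering():
    rng = np.random.default_rng(1)
    mu = rng.normal(size=(6, 4))
    var = rng.uniform(0.1, 2.0, size=(6, 4))
    perm = rng.permutation(6)
    assert kl_term(mu, var) == pytest.approx(kl_term(mu[perm], var[perm]))


# -- negative sampling --------------------------------------------------------

def test_negatives_count_and_disjointness(toy_graph):
    pos = toy_graph.edges["gene-disease"]
    negs = sample_negatives(toy_graph, pos, ratio=1, seed=0)
    assert len(negs) == len(pos)
    assert not negs & pos
    for u, v in negs:
        assert {toy_graph.type_of(u), toy_graph.type_of(v)} == {"gene", "disease"}


def test_negative_sampling_is_seed_deterministic(toy_graph):
    pos = toy_graph.edges["gene-disease"]
    assert sample_negatives(toy_graph, pos, 1, seed=3) == \
        sample_negatives(toy_graph, pos, 1, seed=3)


def test_complete_bipartite_graph_has_no_negatives_to_sample():
    g = HeteroGraph(["d1", "g1"], ["disease", "gene"],
                    {"gene-disease": {("d1", "g1")}})
    with pytest.raises(ValueError, match="non-edges"):
        sample_negatives(g, g.edges["gene-disease"], ratio=1, seed=0)


# -- reconstruction -----------------------------------------------------------

def test_reconstruction_of_one_neutral_positive_is_log_half():
    Z = np.array([[1.0, 0.0], [0.0, 1.0]])  # orthogonal -> inner product 0
    val = reconstruction_term(Z, (np.array([0]), np.array([1])),
                              (np.array([], int), np.array([], int)))
    assert val == pytest.approx(np.log(0.5), abs=1e-12)


def test_reconstruction_of_neutral_positive_and_negative_pair():
    Z = np.array([[1.0, 0.0], [0.0, 1.0]])
    pos = (np.array([0]), np.array([1]))
    neg = (np.array([1]), np.array([0]))
    assert reconstruction_term(Z, pos, neg) == pytest.approx(2 * np.log(0.5))


def test_reconstruction_uses_the_logistic_identity():
    # inner product ln 3 -> sigmoid = 0.75 -> log 0.75
    Z = np.array([[np.log(3.0), 0.0], [1.0, 0.0]])
    val = reconstruction_term(Z, (np.array([0]), np.array([1])),
                              (np.array([], int), np.array([], int)))
    assert val == pytest.approx(np.log(0.75), abs=1e-12)


# -- gradients and the training loop -----------------------------------------

def _setup_loss(seed=0, semantics="multiplicative"):
    rng = np.random.default_rng(seed)
    g = HeteroGraph(
        ["d1", "d2", "g1", "g2", "g3", "g4"],
        ["disease", "disease", "gene", "gene", "gene", "gene"],
        {"gene-gene": {("g1", "g2"), ("g2", "g3")},
         "disease-disease": {("d1", "d2")},
         "gene-disease": {("d1", "g1"), ("d2", "g3"), ("d1", "g4")}})
    mats = normalized_adjacency(g)
    cfg = RgcnConfig(num_layers=2, hidden_dim=4, embedding_dim=4)
    X = rng.standard_normal((6, 5))
    Xstar = rng.standard_normal((6, 4))
    wm = init_weights(cfg, 5, rng, scheme="glorot")
    wd = init_weights(cfg, 4, rng, scheme="glorot")
    pos = _pair_indices(g, sorted(g.edges["gene-disease"]))
    neg = _pair_indices(g, [("d1", "g2"), ("d2", "g4")])
    eps = rng.standard_normal((6, 4))
    tc = TrainConfig(dropout_semantics=semantics)
    return wm, wd, X, Xstar, mats, pos, neg, eps, tc


@pytest.mark.parametrize("semantics", ["multiplicative", "additive"])
def test_analytic_gradients_match_central_finite_differences(semantics):
    wm, wd, X, Xstar, mats, pos, neg, eps, tc = _setup_loss(semantics=semantics)
    kl_weight = 0.5
    _, _, gm, gd = loss_and_grad(wm, wd, X, Xstar, mats, pos, neg, eps,
                                 kl_weight, tc)
    rng = np.random.default_rng(99)
    h = 1e-4
    for wset, grads in ((wm, gm), (wd, gd)):
        for l, layer in enumerate(wset.layers):
            for k in layer:
                W, G = layer[k], grads.layers[l][k]
                for _ in range(4):
                    i, j = np.unravel_index(rng.integers(W.size), W.shape)
                    orig = W[i, j]
                    W[i, j] = orig + h
                    lp = loss_and_grad(wm, wd, X, Xstar, mats, pos, neg, eps,
                                       kl_weight, tc)[0]
                    W[i, j] = orig - h
                    lm = loss_and_grad(wm, wd, X, Xstar, mats, pos, neg, eps,
                                       kl_weight, tc)[0]
                    W[i, j] = orig
                    fd = (lp - lm) / (2 * h)
                    denom = max(abs(fd) + abs(G[i, j]), 1e-8)
                    assert abs(fd - G[i, j]) / denom < 1e-3


def test_adam_reduces_a_simple_quadratic():
    cfg = RgcnConfig(num_layers=1, hidden_dim=2)
    rng = np.random.default_rng(0)
    w = init_weights(cfg, 2, rng, scheme="glorot")
    opt = Adam(w, lr=0.05)
    for _ in range(300):
        grads = type(w)([{k: 2 * v for k, v in layer.items()}
                         for layer in w.layers])
        opt.step(w, grads)
    assert all(np.abs(v).max() < 0.05 for layer in w.layers for v in layer.values())


def _quick_split(graph, seed=0):
    from lupilink import make_split
    return make_split(graph, "general", fold=0, seed=seed)


def test_training_improves_the_elbo_on_a_small_synthetic_graph():
    from lupilink import SynthConfig, generate
    g, feats, _ = generate(SynthConfig(n_genes=30, n_diseases=10, latent_dim=4,
                                       feature_dim_public=8,
                                       feature_dim_privileged=4,
                                       relation_offsets={"gene-gene": -4.0,
                                                         "disease-disease": -4.0,
                                                         "gene-disease": -3.0},
                                       sparse_fraction=0.0, seed=3))
    split = _quick_split(g, seed=1)
    cfg = TrainConfig(epochs=200, seed=1)
    result = train(g, feats, split, RgcnConfig(2, 8), cfg)
    elbos = [row["elbo"] for row in result.history]
    assert elbos[-1] > elbos[0]


def test_learning_rate_defaults_to_1e_minus_4():
    assert TrainConfig().learning_rate == pytest.approx(1e-4)


def test_empty_training_positives_raise(toy_graph, toy_features):
    split = SplitSpec(regime="general", train=set(),
                      val=set(), test=set(toy_graph.edges["gene-disease"]))
    with pytest.raises(ValueError, match="empty"):
        train(toy_graph, toy_features, split, RgcnConfig(1, 4), TrainConfig(epochs=1))


def test_heldout_edges_never_enter_the_training_message_graph(toy_graph, toy_features):
    edges = sorted(toy_graph.edges["gene-disease"])
    split = SplitSpec(regime="general", train=set(edges[:2]), val=set(),
                      test={edges[2]})
    held = edges[2]
    train_graph = toy_graph.subgraph_with_edges(split.train)
    assert held not in train_graph.edges["gene-disease"]
    assert canonical_edge(*held[::-1]) not in train_graph.edges["gene-disease"]
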