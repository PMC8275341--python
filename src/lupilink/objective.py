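"""Variational objective, negative sampling and the training loop.

The model is trained as a variational graph auto-encoder.  The encoder
posterior for node i is a diagonal Gaussian whose mean is the main net's
embedding m_i and whose variance comes from the dropout net; the decoder is
the logistic inner product over gene–disease pairs.  The loss is the
negative evidence lower bound

    -ELBO = -( E_q[log p(A|Z)] - kl_weight * KL[q || N(0, I)] )

with the expectation estimated by a single reparameterized sample per epoch
and the reconstruction term restricted to gene–disease associations (one
uniformly sampled non-edge per positive).  Gradients are computed
analytically (the package does not depend on an autodiff framework) and
checked against finite differences in the test suite.

Two variance semantics are supported, mirroring the two readings of the
multiplicative dropout sample:

* ``multiplicative`` (default): Z_ij = m_ij (1 + sqrt(d_i) eps), so the
  posterior variance entering the KL is m_ij^2 d_i (+ floor).
* ``additive``: Z_ij = m_ij + sqrt(d_i) eps, posterior variance d_i (+ floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .dropout import (DEFAULT_VARIANCE_FLOOR, aggregate_variance,
                      variance_backward)
from .graph import HeteroGraph, canonical_edge
from .metrics import auprc, auroc
from .rgcn import (RgcnConfig, RgcnWeights, encode_backward, encode_forward,
                   init_weights, normalized_adjacency)
from .splits import SplitSpec, sample_nonedges

#: variance added inside the KL so log sigma^2 is finite even where m = 0
KL_VARIANCE_FLOOR = 1e-8


@dataclass
class TrainConfig:
    """Optimization settings; the learning rate defaults to 1e-4 under Adam."""

    learning_rate: float = 1e-4
    epochs: int = 200
    negative_ratio: int = 1
    batch_size: int = 32
    seed: int = 0
    kl_weight: float | str = "auto"  # "auto" = 1 / n_nodes
    aggregator: str = "mean"
    dropout_semantics: str = "multiplicative"
    variance_floor: float = DEFAULT_VARIANCE_FLOOR
    patience: int | None = None
    use_privileged: bool = True
    init_scheme: str = "spectral"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.negative_ratio < 1:
            raise ValueError("negative_ratio must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.dropout_semantics not in ("multiplicative", "additive"):
            raise ValueError(f"unknown dropout_semantics {self.dropout_semantics!r}")

    def resolved_kl_weight(self, n_nodes: int) -> float:
        if self.kl_weight == "auto":
            return 1.0 / n_nodes
        return float(self.kl_weight)


@dataclass
class ElboParts:
    """One epoch's objective decomposition (reconstruction − KL = ELBO)."""

    reconstruction: float
    kl: float

    @property
    def elbo(self) -> float:
        return self.reconstruction - self.kl


def kl_term(mean: np.ndarray, variance: np.ndarray) -> float:
    """Closed-form KL of a diagonal Gaussian posterior against N(0, I).

    Sum over nodes and dimensions of (mu^2 + sigma^2 - 1 - ln sigma^2) / 2.
    """
    mean = np.asarray(mean, float)
    variance = np.asarray(variance, float)
    variance = np.broadcast_to(variance, mean.shape)
    if np.any(variance <= 0):
        raise ValueError("posterior variance must be positive")
    return float(0.5 * np.sum(mean ** 2 + variance - 1.0 - np.log(variance)))


def sample_negatives(graph: HeteroGraph, positives, ratio: int = 1,
                     seed: int | np.random.Generator = 0) -> set[tuple[str, str]]:
    """ratio x |positives| gene–disease non-edges, uniform, distinct, seeded.

    Pairs that are associations anywhere in the full graph are never
    returned, regardless of which split the positives came from.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return sample_nonedges(graph, ratio * len(positives), rng)


def _pair_indices(graph: HeteroGraph, edges) -> tuple[np.ndarray, np.ndarray]:
    idx = graph.index
    us = np.fromiter((idx[u] for u, _ in edges), dtype=int, count=len(edges))
    vs = np.fromiter((idx[v] for _, v in edges), dtype=int, count=len(edges))
    return us, vs


def reconstruction_term(Z: np.ndarray, positives_idx, negatives_idx) -> float:
    """Single-sample estimate of E_q[log p(A | Z)] over sampled pairs.

    positives contribute log sigmoid(<z_u, z_v>), negatives
    log(1 - sigmoid(<z_u, z_v>)); both computed in log space.
    """
    pu, pv = positives_idx
    nu, nv = negatives_idx
    pos_ip = np.einsum("ij,ij->i", Z[pu], Z[pv]) if len(pu) else np.zeros(0)
    neg_ip = np.einsum("ij,ij->i", Z[nu], Z[nv]) if len(nu) else np.zeros(0)
    # log sigmoid(x) = -softplus(-x); log(1 - sigmoid(x)) = -softplus(x)
    softplus = lambda x: np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)
    return float(-np.sum(softplus(-pos_ip)) - np.sum(softplus(neg_ip)))


def reconstruction_term_edges(Z: np.ndarray, graph: HeteroGraph,
                              positives, negatives) -> float:
    """Edge-id convenience wrapper around :func:`reconstruction_term`."""
    return reconstruction_term(Z, _pair_indices(graph, sorted(positives)),
                               _pair_indices(graph, sorted(negatives)))


def loss_and_grad(main_weights: RgcnWeights, dropout_weights: RgcnWeights | None,
                  public_X: np.ndarray, privileged_X: np.ndarray | None,
                  mats, pos_idx, neg_idx, eps: np.ndarray | None,
                  kl_weight: float, config: TrainConfig):
    """-ELBO and its analytic gradients for fixed noise eps and fixed pairs.

    Returns (loss, ElboParts, grad_main, grad_dropout).  ``eps`` is the
    reparameterization draw (same shape as the embedding matrix); passing it
    explicitly makes the loss a deterministic function of the weights, which
    the finite-difference check exploits.  With ``use_privileged`` off the
    model is the deterministic encoder trained on the logistic
    reconstruction likelihood alone.
    """
    m, cache_m = encode_forward(public_X, mats, main_weights, final_activation=False)
    n, e_dim = m.shape
    lupi = config.use_privileged

    if lupi:
        raw, cache_r = encode_forward(privileged_X, mats, dropout_weights,
                                      final_activation=False)
        d = aggregate_variance(raw, g=config.aggregator,
                               variance_floor=config.variance_floor)
        if eps is None:
            eps = np.zeros_like(m)
        sd = np.sqrt(d)[:, None]
        if config.dropout_semantics == "multiplicative":
            Z = m * (1.0 + sd * eps)
            var = m ** 2 * d[:, None] + KL_VARIANCE_FLOOR
        else:
            Z = m + sd * eps
            var = np.broadcast_to(d[:, None], m.shape) + KL_VARIANCE_FLOOR
        kl = kl_term(m, var)
    else:
        d = np.zeros(n)
        Z = m
        kl = 0.0
        kl_weight = 0.0

    pu, pv = pos_idx
    nu, nv = neg_idx
    pos_ip = np.einsum("ij,ij->i", Z[pu], Z[pv])
    neg_ip = np.einsum("ij,ij->i", Z[nu], Z[nv])
    softplus = lambda x: np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)
    recon = float(-np.sum(softplus(-pos_ip)) - np.sum(softplus(neg_ip)))
    loss = -(recon - kl_weight * kl)
    parts = ElboParts(reconstruction=recon, kl=kl_weight * kl)

    # d(-recon)/dZ: for a pair with label y, d recon / d ip = y - sigmoid(ip)
    gZ = np.zeros_like(Z)
    coef_p = expit(pos_ip) - 1.0  # -(1 - sigmoid)
    coef_n = expit(neg_ip)        # -(0 - sigmoid)
    np.add.at(gZ, pu, coef_p[:, None] * Z[pv])
    np.add.at(gZ, pv, coef_p[:, None] * Z[pu])
    np.add.at(gZ, nu, coef_n[:, None] * Z[nv])
    np.add.at(gZ, nv, coef_n[:, None] * Z[nu])

    if not lupi:
        g_input_m = gZ
        grad_main = encode_backward(g_input_m, cache_m, mats, main_weights)[1]
        return loss, parts, grad_main, None

    # chain through the sample and the KL
    if config.dropout_semantics == "multiplicative":
        gm = gZ * (1.0 + sd * eps)
        gd = np.einsum("ij,ij->i", gZ, m * eps) / (2.0 * np.sqrt(d))
        inv_var = 1.0 / var
        gm += kl_weight * (m + (1.0 - inv_var) * m * d[:, None])
        gd += kl_weight * 0.5 * np.einsum("ij,ij->i", (1.0 - inv_var), m ** 2)
    else:
        gm = gZ.copy()
        gd = np.einsum("ij,ij->i", gZ, eps) / (2.0 * np.sqrt(d))
        inv_var = 1.0 / var
        gm += kl_weight * m
        gd += kl_weight * 0.5 * np.sum(1.0 - inv_var, axis=1)

    grad_main = encode_backward(gm, cache_m, mats, main_weights)[1]
    g_raw = variance_backward(gd, raw, d, config.aggregator, config.variance_floor)
    grad_dropout = encode_backward(g_raw, cache_r, mats, dropout_weights)[1]
    return loss, parts, grad_main, grad_dropout


class Adam:
    """Adaptive-moment optimizer over a list of weight dictionaries."""

    def __init__(self, weights: RgcnWeights, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(w) for k, w in layer.items()}
                  for layer in weights.layers]
        self.v = [{k: np.zeros_like(w) for k, w in layer.items()}
                  for layer in weights.layers]

    def step(self, weights: RgcnWeights, grads: RgcnWeights) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for layer, g_layer, m_l, v_l in zip(weights.layers, grads.layers,
                                            self.m, self.v):
            for k in layer:
                g = g_layer[k]
                m_l[k] = self.b1 * m_l[k] + (1 - self.b1) * g
                v_l[k] = self.b2 * v_l[k] + (1 - self.b2) * g * g
                layer[k] -= self.lr * (m_l[k] / b1t) / (np.sqrt(v_l[k] / b2t) + self.eps)


@dataclass
class TrainResult:
    main_weights: RgcnWeights
    dropout_weights: RgcnWeights | None
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1


#: below this many candidate (gene, disease) pairs, validation and test
#: metrics are computed against every non-edge rather than a sample
EXHAUSTIVE_EVAL_MAX_PAIRS = 200_000


def all_nonedges(graph: HeteroGraph) -> list[tuple[str, str]]:
    """Every canonical (gene, disease) pair that is not an association."""
    genes = graph.nodes_of_type("gene")
    diseases = graph.nodes_of_type("disease")
    existing = graph.edges["gene-disease"]
    return sorted(canonical_edge(g, d) for g in genes for d in diseases
                  if canonical_edge(g, d) not in existing)


def train(graph: HeteroGraph, features, split: SplitSpec,
          model_config: RgcnConfig, train_config: TrainConfig) -> TrainResult:
    """Optimize the -ELBO on the training associations.

    One epoch is a full pass over the training positives in mini-batches of
    pairs; the encoder always passes messages over the full training graph
    (training-split gene–disease edges plus all homogeneous edges — no
    neighborhood sampling), and one reparameterized noise draw is shared by
    the epoch's batches.  Negatives are freshly resampled every epoch at
    the configured ratio.  The returned weights are those of the epoch with
    the best validation AUPRC (falling back to the final epoch when there
    is no validation set); validation scoring uses every non-edge when the
    candidate grid is small enough, otherwise the split's sampled
    negatives.
    """
    if not split.train:
        raise ValueError("training positives are empty")
    if not split.train <= graph.edges["gene-disease"]:
        raise ValueError("training edges must be a subset of the graph's associations")
    if split.val & split.train:
        raise ValueError("validation edges must be disjoint from training edges")

    train_graph = graph.subgraph_with_edges(split.train)
    mats = normalized_adjacency(train_graph)
    X = np.asarray(features.public.values, float)
    lupi = train_config.use_privileged
    if lupi:
        if features.privileged is None:
            raise ValueError("privileged features are required to train the LUPI model")
        Xstar = np.asarray(features.privileged.values, float)
    else:
        Xstar = None

    rng = np.random.default_rng(train_config.seed)
    w_main = init_weights(model_config, X.shape[1], rng,
                          scheme=train_config.init_scheme, features=X)
    w_drop = (init_weights(model_config, Xstar.shape[1], rng,
                           scheme=train_config.init_scheme, features=Xstar)
              if lupi else None)
    opt_main = Adam(w_main, lr=train_config.learning_rate)
    opt_drop = Adam(w_drop, lr=train_config.learning_rate) if lupi else None

    pos_sorted = sorted(split.train)
    n_pos = len(pos_sorted)
    ratio = train_config.negative_ratio
    val_pos = sorted(split.val)
    n_genes = len(graph.nodes_of_type("gene"))
    n_diseases = len(graph.nodes_of_type("disease"))
    if val_pos and n_genes * n_diseases <= EXHAUSTIVE_EVAL_MAX_PAIRS:
        val_neg = all_nonedges(graph)
    else:
        val_neg = sorted(split.val_negatives)
    kl_weight = train_config.resolved_kl_weight(graph.n_nodes)

    best_auprc, best_epoch = -np.inf, -1
    best_main, best_drop = w_main.copy(), (w_drop.copy() if lupi else None)
    history: list[dict] = []
    since_best = 0

    for epoch in range(train_config.epochs):
        negs = sorted(sample_negatives(graph, pos_sorted, ratio=ratio, seed=rng))
        eps = rng.standard_normal((graph.n_nodes, model_config.embedding_dim))
        order = rng.permutation(n_pos)
        for start in range(0, n_pos, train_config.batch_size):
            chunk = order[start:start + train_config.batch_size]
            bpos = [pos_sorted[i] for i in chunk]
            bneg = [negs[ratio * i + k] for i in chunk for k in range(ratio)]
            _, _, g_main, g_drop = loss_and_grad(
                w_main, w_drop, X, Xstar, mats,
                _pair_indices(graph, bpos), _pair_indices(graph, bneg), eps,
                kl_weight * len(chunk) / n_pos, train_config)
            opt_main.step(w_main, g_main)
            if lupi:
                opt_drop.step(w_drop, g_drop)

        # epoch-level objective, evaluated once after the epoch's updates
        loss, parts, _, _ = loss_and_grad(
            w_main, w_drop, X, Xstar, mats,
            _pair_indices(graph, pos_sorted), _pair_indices(graph, negs), eps,
            kl_weight, train_config)
        row = {"epoch": epoch, "reconstruction": parts.reconstruction,
               "kl": parts.kl, "elbo": parts.elbo}
        if val_pos:
            m_eval, _ = encode_forward(X, mats, w_main, final_activation=False)
            scores, labels = _pair_scores(graph, m_eval, val_pos, val_neg)
            row["val_auroc"] = auroc(scores, labels)
            row["val_auprc"] = auprc(scores, labels)
            if row["val_auprc"] > best_auprc:
                best_auprc, best_epoch = row["val_auprc"], epoch
                best_main = w_main.copy()
                best_drop = w_drop.copy() if lupi else None
                since_best = 0
            else:
                since_best += 1
        history.append(row)
        if (train_config.patience is not None and val_pos
                and since_best > train_config.patience):
            break

    if not val_pos:
        best_main, best_drop, best_epoch = w_main, w_drop, len(history) - 1
    return TrainResult(main_weights=best_main, dropout_weights=best_drop,
                       history=history, best_epoch=best_epoch)


def _pair_scores(graph: HeteroGraph, emb: np.ndarray, positives, negatives):
    pu, pv = _pair_indices(graph, positives)
    nu, nv = _pair_indices(graph, negatives)
    pos = expit(np.einsum("ij,ij->i", emb[pu], emb[pv]))
    neg = expit(np.einsum("ij,ij->i", emb[nu], emb[nv]))
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return scores, labels
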