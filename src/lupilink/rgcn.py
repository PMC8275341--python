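"""Relational graph convolutional encoder (shared by the main and dropout nets).

One layer computes, for every node i,

    h_i' = act( sum_{r in R} sum_{j in N_i^r} (1/c_ir) W_r h_j  +  W_0 h_i )

with a separate weight matrix W_r per relation, mean normalization
c_ir = |N_i^r| (relations with an empty neighborhood contribute nothing),
a self-connection matrix W_0, and a ReLU activation.  The final layer is
linear by default so embeddings can take either sign, which the
inner-product link decoder requires.

Implemented in NumPy with analytic gradients: ``encode_forward`` caches the
intermediates ``encode_backward`` needs, so the same code path serves both
training and the finite-difference gradient checks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import RELATIONS, HeteroGraph

_ARCH_RE = re.compile(r"^L(\d+)E(\d+)$")


@dataclass
class RgcnConfig:
    """Architecture of one encoder: layer count, width, output dimensionality.

    The compact string "L{a}E{b}" (e.g. "L2E16": two layers, 16 hidden units
    per layer) is accepted wherever a config is expected.  ``embedding_dim``
    defaults to the last hidden width.
    """

    num_layers: int = 2
    hidden_dim: int = 16
    embedding_dim: int | None = None
    relations: tuple[str, ...] = RELATIONS

    def __post_init__(self) -> None:
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.embedding_dim is None:
            self.embedding_dim = self.hidden_dim
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")

    @classmethod
    def from_arch_string(cls, arch: str, embedding_dim: int | None = None) -> "RgcnConfig":
        m = _ARCH_RE.match(arch)
        if not m:
            raise ValueError(f"bad architecture string {arch!r}; expected e.g. 'L2E16'")
        return cls(num_layers=int(m.group(1)), hidden_dim=int(m.group(2)),
                   embedding_dim=embedding_dim)

    @property
    def arch_string(self) -> str:
        return f"L{self.num_layers}E{self.hidden_dim}"

    def layer_dims(self, in_dim: int) -> list[tuple[int, int]]:
        """(input, output) width of each layer given the feature dimension."""
        dims = [in_dim] + [self.hidden_dim] * (self.num_layers - 1) + [self.embedding_dim]
        return list(zip(dims[:-1], dims[1:]))


@dataclass
class RgcnWeights:
    """Per-layer weights: one matrix per relation plus the self matrix W_0."""

    layers: list[dict[str, np.ndarray]] = field(default_factory=list)

    def check_shapes(self, in_dim: int, config: RgcnConfig) -> None:
        dims = config.layer_dims(in_dim)
        if len(self.layers) != len(dims):
            raise ValueError(f"expected {len(dims)} layers, found {len(self.layers)}")
        for layer, (d_in, d_out) in zip(self.layers, dims):
            for key, w in layer.items():
                if w.shape != (d_in, d_out):
                    raise ValueError(
                        f"weight {key!r} has shape {w.shape}, expected {(d_in, d_out)}"
                    )

    def copy(self) -> "RgcnWeights":
        return RgcnWeights([{k: w.copy() for k, w in layer.items()} for layer in self.layers])

    def flat(self) -> list[np.ndarray]:
        return [layer[k] for layer in self.layers for k in sorted(layer)]


def _partial_isometry(d_in: int, d_out: int, rng: np.random.Generator) -> np.ndarray:
    """A d_in x d_out slice of a Haar-random orthogonal matrix (Q^T Q ~ I)."""
    k = max(d_in, d_out)
    a = rng.standard_normal((k, k))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:d_in, :d_out]


#: init scales: self connection, relation (message) matrices, random jitter
_INIT_SELF_SCALE = 0.55
_INIT_REL_SCALE = 0.3
_INIT_NOISE_SCALE = 0.05


def init_weights(config: RgcnConfig, in_dim: int, rng: np.random.Generator,
                 scheme: str = "spectral",
                 features: np.ndarray | None = None) -> RgcnWeights:
    """Initialize per-relation matrices and W_0 for every layer.

    ``spectral`` / ``isometry`` (the defaults) start the encoder as a
    similarity-preserving map so that embedding inner products begin close
    to graph-smoothed feature similarity — the natural prior for
    association scoring — and training refines from there:

    * the first layer's base matrix is the rectifier-transparent pairing
      [Q, -Q] (since relu(a) - relu(-a) = a, the layer keeps a linear
      readout of x Q available to the next layer despite the ReLU), where
      Q holds either the leading principal directions of the supplied
      feature matrix (``spectral``) or a random partial isometry
      (``isometry``);
    * the last layer pairs an isometry as [B; -B], recombining the
      positive and negative halves;
    * every relation matrix starts at a scaled copy of the layer's base
      plus small noise, so message passing begins as neighbor averaging in
      the same coordinate system (neighbors of every relation connect
      nodes with similar latent profiles).

    ``glorot`` gives the conventional uniform fan-in/fan-out init.
    """
    if scheme not in ("spectral", "isometry", "glorot"):
        raise ValueError(f"unknown init scheme {scheme!r}")
    dims = config.layer_dims(in_dim)
    n_layers = len(dims)
    layers = []
    for l, (d_in, d_out) in enumerate(dims):
        glorot = np.sqrt(6.0 / (d_in + d_out))
        if scheme == "glorot":
            layer = {"self": rng.uniform(-glorot, glorot, size=(d_in, d_out))}
            for rel in config.relations:
                layer[rel] = rng.uniform(-glorot, glorot, size=(d_in, d_out))
            layers.append(layer)
            continue
        if l == 0 and n_layers > 1 and d_out % 2 == 0:
            k = d_out // 2
            if (scheme == "spectral" and features is not None
                    and features.shape[1] == d_in and min(features.shape) >= k):
                _, _, vt = np.linalg.svd(np.asarray(features, float),
                                         full_matrices=False)
                q = vt[:k].T
            else:
                q = _partial_isometry(d_in, k, rng)
            base = np.concatenate([q, -q], axis=1)
        elif l == n_layers - 1 and n_layers > 1 and d_in % 2 == 0:
            b = _partial_isometry(d_in // 2, d_out, rng)
            base = np.concatenate([b, -b], axis=0)
        else:
            base = _partial_isometry(d_in, d_out, rng)
        layer = {"self": _INIT_SELF_SCALE * base}
        for rel in config.relations:
            noise = _INIT_NOISE_SCALE * glorot * rng.standard_normal((d_in, d_out))
            layer[rel] = _INIT_REL_SCALE * base + noise
        layers.append(layer)
    return RgcnWeights(layers)


def normalized_adjacency(graph: HeteroGraph) -> dict[str, sp.csr_matrix]:
    """Row-normalized adjacency D_r^{-1} A_r per relation (zero-degree rows stay zero)."""
    mats = {}
    for rel in RELATIONS:
        adj = graph.adjacency(rel).astype(float)
        deg = np.asarray(adj.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        mats[rel] = sp.diags(inv) @ adj
    return mats


def rgcn_layer(h_in: np.ndarray, graph: HeteroGraph, weights: dict[str, np.ndarray],
               apply_activation: bool = True) -> np.ndarray:
    """One message-passing layer on ``graph`` (row order = graph node order)."""
    return _layer_forward(np.asarray(h_in, float), normalized_adjacency(graph),
                          weights, apply_activation)[0]


def _layer_forward(h, mats, weights, apply_activation):
    d_in = h.shape[1]
    if weights["self"].shape[0] != d_in:
        raise ValueError(
            f"input width {d_in} does not match weight shape {weights['self'].shape}"
        )
    pre = h @ weights["self"]
    msgs = {}
    for rel, mat in mats.items():
        m = mat @ h
        msgs[rel] = m
        pre = pre + m @ weights[rel]
    out = np.maximum(pre, 0.0) if apply_activation else pre
    return out, (h, msgs, pre)


def _layer_backward(grad_out, cache, mats, weights, apply_activation):
    h, msgs, pre = cache
    g_pre = grad_out * (pre > 0) if apply_activation else grad_out
    grads = {"self": h.T @ g_pre}
    g_h = g_pre @ weights["self"].T
    for rel, mat in mats.items():
        grads[rel] = msgs[rel].T @ g_pre
        g_h = g_h + mat.T @ (g_pre @ weights[rel].T)
    return g_h, grads


def encode_forward(features: np.ndarray, mats: dict[str, sp.csr_matrix],
                   weights: RgcnWeights, final_activation: bool = False):
    """Run all layers; return (embeddings, cache) for backprop."""
    h = np.asarray(features, float)
    caches = []
    n_layers = len(weights.layers)
    for l, layer_w in enumerate(weights.layers):
        act = True if l < n_layers - 1 else final_activation
        h, cache = _layer_forward(h, mats, layer_w, act)
        caches.append((cache, act))
    return h, caches


def encode_backward(grad_out: np.ndarray, caches, mats, weights: RgcnWeights):
    """Backpropagate through every layer; returns (grad wrt input, weight grads)."""
    g = grad_out
    w_grads: list[dict[str, np.ndarray]] = [None] * len(weights.layers)
    for l in range(len(weights.layers) - 1, -1, -1):
        cache, act = caches[l]
        g, w_grads[l] = _layer_backward(g, cache, mats, weights.layers[l], act)
    return g, RgcnWeights(w_grads)


def encode(features: np.ndarray, graph: HeteroGraph, config: RgcnConfig,
           weights: RgcnWeights, final_activation: bool = False) -> np.ndarray:
    """Deterministic embedding of every node: the composition of all layers."""
    weights.check_shapes(np.asarray(features).shape[1], config)
    emb, _ = encode_forward(features, normalized_adjacency(graph), weights,
                            final_activation)
    return emb
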