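"""Heteroscedastic Gaussian dropout driven by privileged features.

The core idea: a second encoder (the *dropout net*), architecturally
mirroring the main net, maps training-only "privileged" features x* to a
per-node dropout variance d.  The main net's embedding m is then perturbed
multiplicatively,

    v_i = m_i * N(1, d_i)        (elementwise, shared variance per node)

so nodes whose privileged features mark them as unreliable receive noisier
embeddings during training.  At evaluation time the dropout net and the
privileged features are never touched: predictions use v = m exactly, which
is what lets test-time features differ from (or lack) the training ones.

The per-node variance is the aggregate g (mean/sum/median) of the dropout
net's output dimensions after an elementwise softplus, floored at a small
positive constant.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .graph import HeteroGraph
from .rgcn import RgcnConfig, RgcnWeights, encode_forward, normalized_adjacency

AGGREGATORS = ("mean", "sum", "median")

#: lower bound applied to the dropout net's variance output
DEFAULT_VARIANCE_FLOOR = 1e-6


def softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)), overflow-safe."""
    x = np.asarray(x, float)
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def aggregate_variance(raw: np.ndarray, g: str = "mean",
                       variance_floor: float = DEFAULT_VARIANCE_FLOOR) -> np.ndarray:
    """Map the dropout net's raw outputs to one nonnegative variance per node.

    Applies softplus elementwise (positivity), then the aggregator ``g``
    across output dimensions, then the floor.
    """
    if g not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {g!r}; expected one of {AGGREGATORS}")
    raw = np.asarray(raw, float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite dropout-net output")
    s = softplus(raw)
    if g == "mean":
        d = s.mean(axis=1)
    elif g == "sum":
        d = s.sum(axis=1)
    else:
        d = np.median(s, axis=1)
    return np.maximum(d, variance_floor)


def heteroscedastic_sample(mean: np.ndarray, node_variance: np.ndarray,
                           seed: int | np.random.Generator) -> np.ndarray:
    """Draw v_i = m_i * (1 + sqrt(d_i) * eps), eps ~ N(0, 1) iid per entry.

    Each entry of row i is the embedding times a mean-1 Gaussian weight with
    variance d_i.  d_i = 0 is the degenerate case: the sample equals the
    mean exactly.
    """
    mean = np.asarray(mean, float)
    d = np.asarray(node_variance, float)
    if d.ndim != 1 or d.shape[0] != mean.shape[0]:
        raise ValueError("node_variance must be one scalar per node")
    if np.any(d < 0):
        raise ValueError("negative dropout variance")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(mean.shape)
    return mean * (1.0 + np.sqrt(d)[:, None] * eps)


def lupi_forward(public_X: np.ndarray, privileged_Xstar: np.ndarray | None,
                 graph: HeteroGraph, main_weights: RgcnWeights,
                 dropout_weights: RgcnWeights | None, config: RgcnConfig,
                 mode: str = "train", seed: int | np.random.Generator = 0,
                 aggregator: str = "mean",
                 variance_floor: float = DEFAULT_VARIANCE_FLOOR):
    """Full training/evaluation pass of the coupled encoders.

    Train mode returns (m, d, Z): main-net mean, dropout-net per-node
    variance and the sampled embedding.  Eval mode returns (m, zeros, m) —
    the dropout net is never evaluated and privileged features are never
    touched, so they may be absent entirely.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    public_X = np.asarray(public_X, float)
    mats = normalized_adjacency(graph)
    m, _ = encode_forward(public_X, mats, main_weights, final_activation=False)
    if mode == "eval":
        return m, np.zeros(m.shape[0]), m
    if privileged_Xstar is None:
        raise ValueError("privileged features are required in train mode")
    if dropout_weights is None:
        raise ValueError("dropout-net weights are required in train mode")
    raw, _ = encode_forward(np.asarray(privileged_Xstar, float), mats,
                            dropout_weights, final_activation=False)
    d = aggregate_variance(raw, g=aggregator, variance_floor=variance_floor)
    Z = heteroscedastic_sample(m, d, seed)
    return m, d, Z


# -- pieces used by the training loop's analytic backward pass ---------------


def variance_backward(grad_d: np.ndarray, raw: np.ndarray, d: np.ndarray,
                      g: str, variance_floor: float) -> np.ndarray:
    """Gradient of aggregate_variance: route d-gradients back to raw outputs."""
    raw = np.asarray(raw, float)
    n, m_dims = raw.shape
    s = softplus(raw)
    g_s = np.zeros_like(raw)
    if g == "mean":
        g_s[:] = (grad_d / m_dims)[:, None]
    elif g == "sum":
        g_s[:] = grad_d[:, None]
    else:  # median: gradient flows to the middle order statistic(s)
        order = np.argsort(s, axis=1, kind="stable")
        rows = np.arange(n)
        if m_dims % 2 == 1:
            g_s[rows, order[:, m_dims // 2]] = grad_d
        else:
            g_s[rows, order[:, m_dims // 2 - 1]] = 0.5 * grad_d
            g_s[rows, order[:, m_dims // 2]] += 0.5 * grad_d
    # floor: no gradient where the clamp is active
    g_s *= (d > variance_floor)[:, None]
    # softplus derivative is the logistic function
    return g_s * expit(raw)
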