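"""Estimator interface to the LUPI-RGCN variational graph auto-encoder.

:class:`LupiRgcnVgae` follows scikit-learn's estimator conventions:
hyperparameters are constructor arguments, :meth:`fit` learns the weights
and exposes them as trailing-underscore attributes, and
``get_params``/``set_params``/``clone`` work as usual.  The inputs are a
heterogeneous graph, node features and a leakage-safe split rather than a
flat (X, y) pair, so the estimator is used directly rather than inside a
``Pipeline``.

``use_privileged=False`` gives the plain relational-GCN baseline: the same
encoder trained on the logistic reconstruction likelihood alone, with no
dropout net, no sampling and no KL term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from .graph import FeatureMatrix, HeteroGraph, NodeFeatures
from .metrics import EvalReport, auprc, auroc
from .objective import (EXHAUSTIVE_EVAL_MAX_PAIRS, TrainConfig, all_nonedges,
                        train)
from .predict import prediction_table, score_pair
from .rgcn import RgcnConfig, encode_forward, normalized_adjacency
from .splits import SplitSpec


class LupiRgcnVgae(BaseEstimator):
    """Disease–gene link predictor with privileged-information dropout.

    Parameters
    ----------
    architecture:
        Compact encoder description "L{layers}E{units}"; both the main and
        the dropout net use it (the two are always mirrored).
    embedding_dim:
        Output dimensionality; defaults to the architecture's hidden width.
    use_privileged:
        When True, train with the heteroscedastic Gaussian dropout driven
        by privileged features; when False, train the deterministic
        relational-GCN baseline.
    aggregator:
        How the dropout net's output dimensions collapse to one variance
        per node: "mean", "sum" or "median".
    dropout_semantics:
        "multiplicative" (mean-1 Gaussian weight on the embedding) or
        "additive" (the variance enters the posterior directly).
    kl_weight:
        Weight of the KL term; "auto" uses 1/n_nodes.
    """

    def __init__(self, architecture: str = "L2E16", embedding_dim: int | None = None,
                 use_privileged: bool = True, aggregator: str = "mean",
                 dropout_semantics: str = "multiplicative",
                 variance_floor: float = 1e-6, kl_weight="auto",
                 learning_rate: float = 1e-4, epochs: int = 200,
                 negative_ratio: int = 1, batch_size: int = 32,
                 patience: int | None = None, standardize: bool = True,
                 init_scheme: str = "spectral", seed: int = 0):
        self.architecture = architecture
        self.embedding_dim = embedding_dim
        self.use_privileged = use_privileged
        self.aggregator = aggregator
        self.dropout_semantics = dropout_semantics
        self.variance_floor = variance_floor
        self.kl_weight = kl_weight
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.negative_ratio = negative_ratio
        self.batch_size = batch_size
        self.patience = patience
        self.standardize = standardize
        self.init_scheme = init_scheme
        self.seed = seed

    # -- configuration --------------------------------------------------------

    def _model_config(self) -> RgcnConfig:
        return RgcnConfig.from_arch_string(self.architecture,
                                           embedding_dim=self.embedding_dim)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            negative_ratio=self.negative_ratio, batch_size=self.batch_size,
            seed=self.seed, kl_weight=self.kl_weight, aggregator=self.aggregator,
            dropout_semantics=self.dropout_semantics,
            variance_floor=self.variance_floor, patience=self.patience,
            use_privileged=self.use_privileged, init_scheme=self.init_scheme)

    def _fit_scaler(self, fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Column mean/scale over all nodes (no edge labels involved)."""
        mu = fm.values.mean(axis=0)
        sd = fm.values.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return mu, sd

    def _fit_privileged_scaler(self, fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Center columns but scale by one global factor.

        Privileged features encode per-node measurement reliability in
        their magnitudes; per-column unit-variance scaling would inflate
        low-variance nuisance dimensions to the same footing as the
        informative ones and erase exactly the scale structure the dropout
        net is meant to read.
        """
        mu = fm.values.mean(axis=0)
        scale = fm.values.std()
        if scale == 0:
            scale = 1.0
        return mu, np.full(fm.values.shape[1], scale)

    @staticmethod
    def _apply_scaler(fm: FeatureMatrix, mu: np.ndarray, sd: np.ndarray) -> FeatureMatrix:
        vals = (fm.values - mu) / sd
        vals[fm.mask == 0] = 0.0  # missing entries stay exactly zero-filled
        return FeatureMatrix(values=vals, mask=fm.mask.copy())

    # -- fitting --------------------------------------------------------------

    def fit(self, graph: HeteroGraph, features: NodeFeatures,
            split: SplitSpec) -> "LupiRgcnVgae":
        """Train on the split's training associations; select by val AUPRC."""
        if not isinstance(graph, HeteroGraph):
            raise TypeError("graph must be a HeteroGraph")
        if features.public.n_nodes != graph.n_nodes:
            raise ValueError("feature rows must align with graph nodes")
        if self.standardize:
            self.scaler_ = self._fit_scaler(features.public)
            public = self._apply_scaler(features.public, *self.scaler_)
            privileged = features.privileged
            if privileged is not None:
                priv_scaler = self._fit_privileged_scaler(privileged)
                privileged = self._apply_scaler(privileged, *priv_scaler)
            features = NodeFeatures(public=public, privileged=privileged)
        else:
            self.scaler_ = None
        result = train(graph, features, split, self._model_config(),
                       self._train_config())
        self.main_weights_ = result.main_weights
        self.dropout_weights_ = result.dropout_weights
        self.history_ = pd.DataFrame(result.history)
        self.best_epoch_ = result.best_epoch
        self.graph_ = graph
        self.split_ = split
        self.n_features_in_ = features.public.n_dims
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "main_weights_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    # -- inference ------------------------------------------------------------

    def transform(self, public_features: FeatureMatrix | np.ndarray,
                  message_edges: str = "train+val") -> np.ndarray:
        """Mean embeddings of every node (the dropout net plays no role here).

        ``message_edges`` selects which gene–disease associations the
        encoder may pass messages over: "train" or "train+val" (test edges
        are never visible).
        """
        self._check_fitted()
        raw = public_features.values if isinstance(public_features, FeatureMatrix) \
            else np.asarray(public_features, float)
        if raw.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature dims, got {raw.shape[1]}")
        if isinstance(public_features, FeatureMatrix):
            X = (self._apply_scaler(public_features, *self.scaler_).values
                 if self.scaler_ is not None else raw)
        else:
            X = ((raw - self.scaler_[0]) / self.scaler_[1]
                 if self.scaler_ is not None else raw)
        if message_edges == "train":
            scope = self.split_.train
        elif message_edges == "train+val":
            scope = self.split_.train | self.split_.val
        else:
            raise ValueError("message_edges must be 'train' or 'train+val'")
        eval_graph = self.graph_.subgraph_with_edges(scope)
        mats = normalized_adjacency(eval_graph)
        emb, _ = encode_forward(X, mats, self.main_weights_, final_activation=False)
        return emb

    def predict_proba(self, pairs, public_features) -> np.ndarray:
        """Association probability for each (gene_id, disease_id) pair."""
        emb = self.transform(public_features)
        idx = self.graph_.index
        return np.array([score_pair(emb[idx[g]], emb[idx[d]]) for g, d in pairs])

    def predict(self, pairs, public_features, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(pairs, public_features) >= threshold).astype(int)

    def prediction_table(self, public_features, diseases=None, top_k=None,
                         exclude_train: bool = True) -> pd.DataFrame:
        """Ranked per-disease candidate table (see :mod:`lupilink.predict`)."""
        emb = self.transform(public_features)
        exclude = (self.split_.train | self.split_.val) if exclude_train else None
        return prediction_table(emb, self.graph_, diseases=diseases,
                                exclude_edges=exclude, top_k=top_k)

    def evaluate(self, public_features, positives=None, negatives=None,
                 regime: str | None = None) -> EvalReport:
        """AUROC/AUPRC on held-out pairs (defaults: the split's test set).

        When no negatives are given, every non-association in the candidate
        grid is used as a negative if the grid is small enough, matching
        the exhaustive evaluation a ranking of all candidates implies;
        otherwise the split's sampled negatives are used.
        """
        self._check_fitted()
        g = self.graph_
        positives = sorted(positives if positives is not None else self.split_.test)
        if negatives is None:
            n_pairs = (len(g.nodes_of_type("gene")) * len(g.nodes_of_type("disease")))
            if n_pairs <= EXHAUSTIVE_EVAL_MAX_PAIRS:
                negatives = all_nonedges(g)
            else:
                negatives = sorted(self.split_.test_negatives)
        else:
            negatives = sorted(negatives)
        emb = self.transform(public_features)
        idx = g.index
        pu = np.array([idx[u] for u, _ in positives], dtype=int)
        pv = np.array([idx[v] for _, v in positives], dtype=int)
        nu = np.array([idx[u] for u, _ in negatives], dtype=int)
        nv = np.array([idx[v] for _, v in negatives], dtype=int)
        ips = np.einsum("ij,ij->i", emb[pu], emb[pv])
        ins = np.einsum("ij,ij->i", emb[nu], emb[nv])
        scores = expit(np.concatenate([ips, ins]))
        labels = np.concatenate([np.ones(len(ips)), np.zeros(len(ins))])
        return EvalReport(regime=regime or self.split_.regime,
                          auroc=auroc(scores, labels),
                          auprc=auprc(scores, labels),
                          fold=self.split_.fold_id, seed=self.seed)
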