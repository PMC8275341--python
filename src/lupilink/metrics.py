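"""Ranking metrics for disease–gene link prediction.

AUROC is the rank statistic (probability a random positive outscores a
random negative, ties counted one half); AUPRC is average precision over
the descending-score threshold sweep, with no interpolation.  recall@K is
micro-averaged over held-out associations: the fraction whose gene appears
in the inclusive top-K candidates ranked for its disease.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


def auroc(scores, labels) -> float:
    """Area under the ROC curve; requires both classes present."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both a positive and a negative example")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Average precision (area under the precision-recall step curve)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels length mismatch")
    if labels.sum() == 0:
        raise ValueError("AUPRC needs at least one positive example")
    return float(average_precision_score(labels, scores))


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def f1_at_threshold(scores, labels, threshold: float = 0.5) -> float:
    """F1 of the classifier 'score >= threshold', convenience for reports."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pred = scores >= threshold
    tp = int(np.sum(pred & labels))
    precision = tp / pred.sum() if pred.sum() else 0.0
    recall = tp / labels.sum() if labels.sum() else 0.0
    return f1(precision, recall)


def recall_at_k(test_edges, predictions: pd.DataFrame, K: int) -> float:
    """Fraction of held-out (gene, disease) associations retrieved in the top K.

    ``predictions`` is a ranked table with columns disease_id, gene_id, rank
    (1-based within each disease).  A held-out association counts as
    retrieved when its gene's rank for its disease is <= K (inclusive).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    in_top = {
        (d, g)
        for d, g, r in predictions[["disease_id", "gene_id", "rank"]].itertuples(index=False)
        if r <= K
    }
    hits = 0
    for u, v in test_edges:
        # canonical edges do not record which endpoint is the disease
        if (u, v) in in_top or (v, u) in in_top:
            hits += 1
    return hits / len(test_edges) if test_edges else 0.0


@dataclass
class EvalReport:
    """Metrics for one (regime, fold, masking level) cell of an experiment."""

    regime: str
    auroc: float
    auprc: float
    f1: float | None = None
    recall_at_k: dict[int, float] | None = None
    masking_k: float | None = None
    fold: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)
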