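"""Scoring and ranking of candidate disease–gene associations.

At prediction time only the main net's mean embeddings are used: the score
for a (gene, disease) pair is the logistic function of the inner product of
the two embeddings.  Rankings are deterministic — descending score, ties
broken by ascending gene id — and known training positives are excluded
from a disease's candidate list by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .graph import HeteroGraph

#: clip bounds keeping reported scores strictly inside (0, 1)
_SCORE_EPS = 1e-300
_SCORE_TOP = 1e-16


def score_pair(emb_gene: np.ndarray, emb_disease: np.ndarray) -> float:
    """Association probability: sigmoid of the embedding inner product."""
    emb_gene = np.asarray(emb_gene, float)
    emb_disease = np.asarray(emb_disease, float)
    if emb_gene.shape != emb_disease.shape:
        raise ValueError(
            f"embedding dimensions differ: {emb_gene.shape} vs {emb_disease.shape}"
        )
    s = float(expit(np.dot(emb_gene, emb_disease)))
    return min(max(s, _SCORE_EPS), 1.0 - _SCORE_TOP)


def log_score_pair(emb_gene: np.ndarray, emb_disease: np.ndarray) -> float:
    """log of the association probability, stable for strongly negative inner products."""
    x = float(np.dot(np.asarray(emb_gene, float), np.asarray(emb_disease, float)))
    # log sigmoid(x) = -softplus(-x)
    return -(np.log1p(np.exp(-abs(x))) + max(-x, 0.0))


def rank_genes(disease_id: str, candidate_genes: list[str], embeddings: np.ndarray,
               graph: HeteroGraph, exclude: set | None = None) -> list[tuple[str, float]]:
    """Rank candidate genes for one disease, best first.

    ``exclude`` holds known (training) associations as canonical edges or
    gene ids; matching candidates are removed before ranking.
    """
    if disease_id not in graph.index:
        raise KeyError(f"unknown disease id {disease_id!r}")
    excluded_genes = set()
    for item in exclude or ():
        if isinstance(item, tuple):
            u, v = item
            if u == disease_id:
                excluded_genes.add(v)
            elif v == disease_id:
                excluded_genes.add(u)
        else:
            excluded_genes.add(item)
    pool = [g for g in candidate_genes if g not in excluded_genes]
    d_emb = embeddings[graph.index[disease_id]]
    scored = [(g, score_pair(embeddings[graph.index[g]], d_emb)) for g in pool]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def prediction_table(embeddings: np.ndarray, graph: HeteroGraph,
                     diseases: list[str] | None = None,
                     candidate_genes: list[str] | None = None,
                     exclude_edges: set | None = None,
                     top_k: int | None = None) -> pd.DataFrame:
    """Ranked predictions for every requested disease as one tidy table.

    Columns: disease_id, gene_id, score, rank (1-based per disease).
    """
    if diseases is None:
        diseases = graph.nodes_of_type("disease")
    if candidate_genes is None:
        candidate_genes = graph.nodes_of_type("gene")
    rows = []
    for d in diseases:
        ranked = rank_genes(d, candidate_genes, embeddings, graph,
                            exclude=exclude_edges)
        if top_k is not None:
            ranked = ranked[:top_k]
        for r, (g, s) in enumerate(ranked, start=1):
            rows.append((d, g, s, r))
    return pd.DataFrame(rows, columns=["disease_id", "gene_id", "score", "rank"])


def write_predictions(table: pd.DataFrame, path) -> None:
    """Write the prediction table as TSV with a fixed float format (byte-stable)."""
    out = table.copy()
    out["score"] = out["score"].map(lambda s: f"{s:.12g}")
    out.to_csv(path, sep="\t", index=False)
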