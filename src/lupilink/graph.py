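"""Heterogeneous disease–gene graph container and plain-text I/O.

The graph has two node types (``disease``, ``gene``) and three undirected
relations: ``gene-gene`` (functional similarity), ``disease-disease``
(phenotype similarity) and ``gene-disease`` (known associations).  Every
edge is stored exactly once in canonical form — the endpoint with the
lexicographically smaller node id first — so that an association i–j and
its mirror j–i can never end up in different train/test splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

NODE_TYPES = ("disease", "gene")
RELATIONS = ("gene-gene", "disease-disease", "gene-disease")

#: node-type pair each relation is allowed to connect (as a set for symmetry)
_RELATION_TYPES = {
    "gene-gene": frozenset({"gene"}),
    "disease-disease": frozenset({"disease"}),
    "gene-disease": frozenset({"gene", "disease"}),
}


class GraphValidationError(ValueError):
    """Raised when a node table / edge list violates a structural invariant."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the undirected edge (u, v) with the lexicographically smaller id first."""
    return (u, v) if u <= v else (v, u)


@dataclass
class HeteroGraph:
    """Typed nodes plus three undirected relation edge sets.

    Parameters
    ----------
    node_ids:
        Node identifiers in table order; this order fixes the row order of
        every feature matrix and embedding matrix.
    node_types:
        One of ``disease`` / ``gene`` per node, aligned with ``node_ids``.
    edges:
        Mapping relation -> set of canonical (u, v) id pairs.
    """

    node_ids: list[str]
    node_types: list[str]
    edges: dict[str, set[tuple[str, str]]]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(self.node_types):
            raise GraphValidationError("node_ids and node_types length mismatch")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise GraphValidationError("duplicate node ids in node table")
        for t in self.node_types:
            if t not in NODE_TYPES:
                raise GraphValidationError(f"unknown node type {t!r}")
        self.index = {nid: i for i, nid in enumerate(self.node_ids)}
        for rel in self.edges:
            if rel not in RELATIONS:
                raise GraphValidationError(f"unknown relation {rel!r}")
        for rel in RELATIONS:
            self.edges.setdefault(rel, set())
        self._validate_edges()

    # -- construction helpers -------------------------------------------------

    def _validate_edges(self) -> None:
        for rel, pairs in self.edges.items():
            allowed = _RELATION_TYPES[rel]
            for u, v in pairs:
                if u == v:
                    raise GraphValidationError(f"self-loop {u!r} under relation {rel}")
                for nid in (u, v):
                    if nid not in self.index:
                        raise GraphValidationError(
                            f"edge ({u!r}, {v!r}) references unknown node id {nid!r}"
                        )
                types = {self.type_of(u), self.type_of(v)}
                if types != allowed:
                    raise GraphValidationError(
                        f"edge ({u!r}, {v!r}) endpoint types {sorted(types)} "
                        f"do not match relation {rel}"
                    )
                if canonical_edge(u, v) != (u, v):
                    raise GraphValidationError(
                        f"edge ({u!r}, {v!r}) stored in non-canonical orientation"
                    )

    # -- queries --------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def type_of(self, node_id: str) -> str:
        return self.node_types[self.index[node_id]]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, t in zip(self.node_ids, self.node_types) if t == node_type]

    def has_edge(self, u: str, v: str, relation: str) -> bool:
        return canonical_edge(u, v) in self.edges[relation]

    def num_edges(self, relation: str | None = None) -> int:
        if relation is not None:
            return len(self.edges[relation])
        return sum(len(p) for p in self.edges.values())

    def neighbors(self, node_id: str, relation: str) -> list[str]:
        """N_i^r: neighbors of ``node_id`` under ``relation``."""
        out = []
        for u, v in self.edges[relation]:
            if u == node_id:
                out.append(v)
            elif v == node_id:
                out.append(u)
        return sorted(out)

    def degree(self, node_id: str, relation: str) -> int:
        """c_ir = |N_i^r|, the per-relation normalization count."""
        return len(self.neighbors(node_id, relation))

    def adjacency(self, relation: str) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency of one relation in node-table order."""
        n = self.n_nodes
        pairs = self.edges[relation]
        if not pairs:
            return sp.csr_matrix((n, n))
        rows, cols = [], []
        for u, v in pairs:
            i, j = self.index[u], self.index[v]
            rows += [i, j]
            cols += [j, i]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    def degree_vector(self, relation: str) -> np.ndarray:
        """c_ir for every node, in node-table order."""
        adj = self.adjacency(relation)
        return np.asarray(adj.sum(axis=1)).ravel()

    def subgraph_with_edges(self, gene_disease_edges: set[tuple[str, str]]) -> "HeteroGraph":
        """Same nodes and homogeneous relations, but only the given gene-disease edges.

        Used to restrict message passing to the training (or train+val)
        associations so held-out edges are invisible to the encoder.
        """
        edges = {
            "gene-gene": set(self.edges["gene-gene"]),
            "disease-disease": set(self.edges["disease-disease"]),
            "gene-disease": {canonical_edge(*e) for e in gene_disease_edges},
        }
        return HeteroGraph(list(self.node_ids), list(self.node_types), edges)

    def relation_counts(self) -> dict[str, int]:
        return {rel: len(self.edges[rel]) for rel in RELATIONS}


@dataclass
class FeatureMatrix:
    """One half of the node features: a dense matrix plus an observedness mask.

    Rows align with the graph's node order; entries whose mask is 0 hold the
    value 0 exactly (missingness is zero-filled, never imputed or dropped).
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.values.shape != self.mask.shape:
            raise GraphValidationError("feature values and mask shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise GraphValidationError("non-finite feature value")
        if np.any(self.values[self.mask == 0] != 0.0):
            raise GraphValidationError("masked-out entries must be exactly zero")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]

    def nonzero_fraction(self) -> np.ndarray:
        """Per-node fraction of nonzero feature entries, in [0, 1]."""
        return (self.values != 0).mean(axis=1)


@dataclass
class NodeFeatures:
    """Public (always available) and privileged (train-only) feature halves."""

    public: FeatureMatrix
    privileged: FeatureMatrix | None = None

    def __post_init__(self) -> None:
        if self.privileged is not None and self.privileged.n_nodes != self.public.n_nodes:
            raise GraphValidationError("public/privileged row counts differ")


# -- file formats -------------------------------------------------------------


def read_graph(node_table_path, edge_list_path) -> HeteroGraph:
    """Read a node table and an edge list into a validated :class:`HeteroGraph`.

    The node table is a TSV with columns ``node_id``, ``node_type``; the edge
    list a TSV with columns ``u``, ``v``, ``relation``.  Reversed or repeated
    edge rows collapse to one canonical edge.
    """
    nodes = pd.read_csv(node_table_path, sep="\t", dtype=str)
    for col in ("node_id", "node_type"):
        if col not in nodes.columns:
            raise GraphValidationError(f"node table missing column {col!r}")
    edge_df = pd.read_csv(edge_list_path, sep="\t", dtype=str)
    for col in ("u", "v", "relation"):
        if col not in edge_df.columns:
            raise GraphValidationError(f"edge list missing column {col!r}")

    edges: dict[str, set[tuple[str, str]]] = {rel: set() for rel in RELATIONS}
    for u, v, rel in edge_df[["u", "v", "relation"]].itertuples(index=False):
        if rel not in RELATIONS:
            raise GraphValidationError(f"unknown relation {rel!r} on edge ({u!r}, {v!r})")
        if u == v:
            raise GraphValidationError(f"self-loop {u!r} under relation {rel}")
        edges[rel].add(canonical_edge(u, v))
    return HeteroGraph(
        node_ids=nodes["node_id"].tolist(),
        node_types=nodes["node_type"].tolist(),
        edges=edges,
    )


def write_graph(graph: HeteroGraph, node_table_path, edge_list_path) -> None:
    """Write the node table and canonical edge list as TSV (round-trips with read_graph)."""
    pd.DataFrame({"node_id": graph.node_ids, "node_type": graph.node_types}).to_csv(
        node_table_path, sep="\t", index=False
    )
    rows = []
    for rel in RELATIONS:
        for u, v in sorted(graph.edges[rel]):
            rows.append((u, v, rel))
    pd.DataFrame(rows, columns=["u", "v", "relation"]).to_csv(
        edge_list_path, sep="\t", index=False
    )


def read_features(matrix_path, node_order: list[str], row_id_path=None) -> FeatureMatrix:
    """Load one feature half and align its rows to ``node_order``.

    Two on-disk layouts are supported: a dense TSV whose first column is
    ``node_id``, or a Matrix-Market coordinate file plus a one-id-per-line
    row sidecar (``row_id_path``).  Nodes without a row become all-zero with
    an all-zero mask, so sparse-feature nodes stay in the model instead of
    being dropped.
    """
    if row_id_path is not None or str(matrix_path).endswith((".mtx", ".mtx.gz")):
        if row_id_path is None:
            raise GraphValidationError("Matrix-Market features need a row-id sidecar file")
        mat = sp.coo_matrix(scipy.io.mmread(matrix_path))
        with open(row_id_path) as fh:
            row_ids = [line.strip() for line in fh if line.strip()]
        if mat.shape[0] != len(row_ids):
            raise GraphValidationError(
                f"matrix has {mat.shape[0]} rows but sidecar lists {len(row_ids)} ids"
            )
        dense = np.asarray(mat.todense(), dtype=float)
        frame = pd.DataFrame(dense, index=row_ids)
    else:
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)

    known = set(node_order)
    for rid in frame.index:
        if rid not in known:
            raise GraphValidationError(f"feature row id {rid!r} not in node table")
    if not np.all(np.isfinite(frame.to_numpy(dtype=float))):
        raise GraphValidationError("non-finite value in feature matrix")

    n_dims = frame.shape[1]
    values = np.zeros((len(node_order), n_dims))
    mask = np.zeros((len(node_order), n_dims), dtype=np.int8)
    pos = {rid: k for k, rid in enumerate(frame.index)}
    arr = frame.to_numpy(dtype=float)
    for i, nid in enumerate(node_order):
        if nid in pos:
            values[i] = arr[pos[nid]]
            mask[i] = 1
    return FeatureMatrix(values=values, mask=mask)


def write_features(features: FeatureMatrix, node_order: list[str], matrix_path) -> None:
    """Write a dense TSV (first column node_id); rows with all-zero mask are omitted."""
    keep = features.mask.any(axis=1)
    frame = pd.DataFrame(
        features.values[keep],
        index=pd.Index(np.asarray(node_order)[keep], name="node_id"),
        columns=[f"f{j}" for j in range(features.n_dims)],
    )
    frame.to_csv(matrix_path, sep="\t", float_format="%.10g")


def feature_sparsity_histogram(features: FeatureMatrix, node_order: list[str],
                               bins: int = 10) -> pd.DataFrame:
    """Per-node nonzero fraction plus a binned summary (distribution of feature sparsity).

    Returns a frame with columns ``node_id``, ``nonzero_fraction`` and a
    ``bin`` label assigning each node to one of ``bins`` equal-width bins
    over [0, 1].
    """
    frac = features.nonzero_fraction()
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(frac, edges[1:-1], right=False), 0, bins - 1)
    return pd.DataFrame(
        {
            "node_id": node_order,
            "nonzero_fraction": frac,
            "bin": [f"[{edges[k]:.2f},{edges[k + 1]:.2f})" for k in idx],
        }
    )
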