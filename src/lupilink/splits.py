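"""Leakage-safe train/validation/test splits over gene–disease associations.

All splitting operates on canonical undirected edges, so an association and
its reversed duplicate can never land in different partitions.  Four
evaluation regimes are supported:

``general``
    10-fold cross-validation: per fold 80% train / 10% val / 10% test, each
    association in test exactly once across the folds.
``new_disease``
    A fraction of diseases is held out; all their associations form the
    test set, so test diseases have no association in train or val.
``new_association``
    Both a disease and a gene set are held out; test edges connect a
    held-out gene to a held-out disease, and neither endpoint retains any
    association in train or val (edges touching exactly one held-out
    endpoint are discarded).
``singleton``
    Test edges are the single association of every gene whose gene–disease
    degree in the full graph is exactly 1 (the network signal is weakest
    there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import HeteroGraph, canonical_edge

REGIMES = ("general", "new_disease", "new_association", "singleton")

Edge = tuple[str, str]


class SplitError(ValueError):
    """Raised when a regime cannot be satisfied on the given graph."""


@dataclass
class SplitSpec:
    """Disjoint canonical gene–disease edge partitions plus sampled negatives."""

    regime: str
    train: set[Edge]
    val: set[Edge]
    test: set[Edge]
    test_negatives: set[Edge] = field(default_factory=set)
    val_negatives: set[Edge] = field(default_factory=set)
    fold_id: int = 0
    seed: int = 0

    def all_positives(self) -> set[Edge]:
        return self.train | self.val | self.test


def sample_nonedges(graph: HeteroGraph, count: int, rng: np.random.Generator,
                    forbidden: set[Edge] | None = None) -> set[Edge]:
    """Uniformly sample ``count`` distinct (gene, disease) non-edges.

    Pairs must not be gene-disease edges anywhere in the full graph; extra
    pairs in ``forbidden`` (e.g. negatives already drawn for another
    partition) are excluded too.
    """
    genes = graph.nodes_of_type("gene")
    diseases = graph.nodes_of_type("disease")
    if not genes or not diseases:
        raise SplitError("graph needs at least one gene and one disease")
    existing = set(graph.edges["gene-disease"])
    if forbidden:
        existing = existing | {canonical_edge(*e) for e in forbidden}
    available = len(genes) * len(diseases) - len(existing)
    if count > available:
        raise SplitError(
            f"requested {count} negative pairs but only {available} non-edges exist"
        )
    chosen: set[Edge] = set()
    genes = np.asarray(genes)
    diseases = np.asarray(diseases)
    while len(chosen) < count:
        k = max(count - len(chosen), 16)
        gs = genes[rng.integers(0, len(genes), size=2 * k)]
        ds = diseases[rng.integers(0, len(diseases), size=2 * k)]
        for g, d in zip(gs, ds):
            e = canonical_edge(str(g), str(d))
            if e not in existing and e not in chosen:
                chosen.add(e)
                if len(chosen) == count:
                    break
    return chosen


def _split_remaining(edges: list[Edge], rng: np.random.Generator,
                     val_fraction: float = 0.1) -> tuple[set[Edge], set[Edge]]:
    edges = list(edges)
    rng.shuffle(edges)
    n_val = int(round(val_fraction * len(edges)))
    return set(edges[n_val:]), set(edges[:n_val])


def make_split(graph: HeteroGraph, regime: str, fold: int = 0, seed: int = 0,
               n_folds: int = 10, holdout_fraction: float = 0.1,
               negative_ratio: int = 1) -> SplitSpec:
    """Build one leakage-safe :class:`SplitSpec` for the requested regime."""
    if regime not in REGIMES:
        raise SplitError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    edges = sorted(graph.edges["gene-disease"])
    if not edges:
        raise SplitError("graph has no gene-disease associations to split")
    rng = np.random.default_rng(seed)

    if regime == "general":
        if not 0 <= fold < n_folds:
            raise SplitError(f"fold must be in [0, {n_folds}), got {fold}")
        if len(edges) < n_folds:
            raise SplitError(f"need at least {n_folds} associations for {n_folds} folds")
        perm = list(edges)
        rng.shuffle(perm)  # one permutation per seed shared by all folds
        chunks = np.array_split(np.arange(len(perm)), n_folds)
        test = {perm[i] for i in chunks[fold]}
        val = {perm[i] for i in chunks[(fold + 1) % n_folds]}
        train = set(perm) - test - val
    elif regime == "new_disease":
        active = sorted({d for e in edges for d in e if graph.type_of(d) == "disease"})
        n_hold = max(1, int(round(holdout_fraction * len(active))))
        held = set(rng.choice(np.asarray(active), size=n_hold, replace=False).tolist())
        test = {e for e in edges if e[0] in held or e[1] in held}
        if not test:
            raise SplitError("new_disease regime: no associations touch held-out diseases")
        train, val = _split_remaining([e for e in edges if e not in test], rng)
    elif regime == "new_association":
        act_d = sorted({x for e in edges for x in e if graph.type_of(x) == "disease"})
        act_g = sorted({x for e in edges for x in e if graph.type_of(x) == "gene"})
        n_d = max(1, int(round(holdout_fraction * len(act_d))))
        n_g = max(1, int(round(holdout_fraction * len(act_g))))
        held_d = set(rng.choice(np.asarray(act_d), size=n_d, replace=False).tolist())
        held_g = set(rng.choice(np.asarray(act_g), size=n_g, replace=False).tolist())
        held = held_d | held_g
        test = {e for e in edges if e[0] in held and e[1] in held}
        if not test:
            raise SplitError(
                "new_association regime: no association joins a held-out gene "
                "to a held-out disease; enlarge holdout_fraction or the graph"
            )
        # edges with exactly one held-out endpoint are dropped entirely
        rest = [e for e in edges if e[0] not in held and e[1] not in held]
        train, val = _split_remaining(rest, rng)
    else:  # singleton
        gd_degree: dict[str, int] = {}
        for u, v in edges:
            g = u if graph.type_of(u) == "gene" else v
            gd_degree[g] = gd_degree.get(g, 0) + 1
        singles = {g for g, c in gd_degree.items() if c == 1}
        if not singles:
            raise SplitError("singleton regime: no gene has exactly one association")
        test = {e for e in edges
                if (e[0] in singles and graph.type_of(e[0]) == "gene")
                or (e[1] in singles and graph.type_of(e[1]) == "gene")}
        train, val = _split_remaining([e for e in edges if e not in test], rng)

    if not train:
        raise SplitError(f"{regime} regime left no training associations")
    test_neg = sample_nonedges(graph, negative_ratio * len(test), rng)
    val_neg = sample_nonedges(graph, negative_ratio * len(val), rng, forbidden=test_neg) \
        if val else set()
    return SplitSpec(regime=regime, train=train, val=val, test=test,
                     test_negatives=test_neg, val_negatives=val_neg,
                     fold_id=fold, seed=seed)


@dataclass
class LeakageReport:
    passed: bool
    problems: list[str]


def leakage_check(split: SplitSpec, graph: HeteroGraph) -> LeakageReport:
    """Verify pairwise disjointness (both orientations) and regime invariants."""
    problems: list[str] = []
    parts = {"train": split.train, "val": split.val, "test": split.test}
    canon = {name: {canonical_edge(*e) for e in part} for name, part in parts.items()}
    for a in ("train", "val"):
        for b in ("val", "test"):
            if a == b:
                continue
            overlap = canon[a] & canon[b]
            for e in sorted(overlap):
                problems.append(f"edge {e} appears in both {a} and {b}")
    pos = canon["train"] | canon["val"] | canon["test"]
    for e in sorted({canonical_edge(*x) for x in split.test_negatives} & pos):
        problems.append(f"test negative {e} is a positive edge")

    def _disease(e: Edge) -> str:
        return e[0] if graph.type_of(e[0]) == "disease" else e[1]

    def _gene(e: Edge) -> str:
        return e[0] if graph.type_of(e[0]) == "gene" else e[1]

    trainval = canon["train"] | canon["val"]
    if split.regime == "new_disease":
        test_d = {_disease(e) for e in canon["test"]}
        for e in sorted(trainval):
            if _disease(e) in test_d:
                problems.append(f"test disease {_disease(e)} retains train/val edge {e}")
    elif split.regime == "new_association":
        test_d = {_disease(e) for e in canon["test"]}
        test_g = {_gene(e) for e in canon["test"]}
        for e in sorted(trainval):
            if _disease(e) in test_d or _gene(e) in test_g:
                problems.append(f"held-out endpoint of {e} appears in train/val")
    elif split.regime == "singleton":
        for e in sorted(canon["test"]):
            g = _gene(e)
            if graph.degree(g, "gene-disease") != 1:
                problems.append(f"test gene {g} has gene-disease degree != 1")
        test_g = {_gene(e) for e in canon["test"]}
        for e in sorted(trainval):
            if _gene(e) in test_g:
                problems.append(f"singleton gene {_gene(e)} retains train/val edge {e}")
    return LeakageReport(passed=not problems, problems=problems)


def mask_features(features, keep_percent: float, scope: set[str],
                  node_order: list[str], seed: int = 0):
    """Keep a random ``keep_percent``% of feature dimensions per node in scope.

    The complementary dimensions are zeroed with mask 0 (emulating features
    unmeasured at test time).  scope = empty set is the identity; the number
    of retained dimensions is round(k/100 * n_dims), drawn independently
    and uniformly per node.
    """
    from .graph import FeatureMatrix

    if not 0.0 <= keep_percent <= 100.0:
        raise ValueError("keep_percent must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    values = features.values.copy()
    mask = features.mask.copy()
    n_keep = int(round(keep_percent / 100.0 * features.n_dims))
    for i, nid in enumerate(node_order):
        if nid not in scope:
            continue
        kept = rng.choice(features.n_dims, size=n_keep, replace=False)
        drop = np.ones(features.n_dims, dtype=bool)
        drop[kept] = False
        values[i, drop] = 0.0
        mask[i, drop] = 0
    return FeatureMatrix(values=values, mask=mask)


# -- split files --------------------------------------------------------------


def write_split(split: SplitSpec, path) -> None:
    rows = []
    for name in ("train", "val", "test"):
        for u, v in sorted(getattr(split, name)):
            rows.append((u, v, "gene-disease", name, split.fold_id, split.regime))
    for u, v in sorted(split.test_negatives):
        rows.append((u, v, "gene-disease", "test_negative", split.fold_id, split.regime))
    for u, v in sorted(split.val_negatives):
        rows.append((u, v, "gene-disease", "val_negative", split.fold_id, split.regime))
    pd.DataFrame(rows, columns=["u", "v", "relation", "split", "fold", "regime"]).to_csv(
        path, sep="\t", index=False
    )


def read_split(path) -> SplitSpec:
    df = pd.read_csv(path, sep="\t", dtype={"u": str, "v": str})
    parts = {name: set() for name in ("train", "val", "test",
                                      "test_negative", "val_negative")}
    for u, v, name in df[["u", "v", "split"]].itertuples(index=False):
        parts[name].add(canonical_edge(u, v))
    return SplitSpec(
        regime=str(df["regime"].iloc[0]),
        train=parts["train"], val=parts["val"], test=parts["test"],
        test_negatives=parts["test_negative"], val_negatives=parts["val_negative"],
        fold_id=int(df["fold"].iloc[0]),
    )
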