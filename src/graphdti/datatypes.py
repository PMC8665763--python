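"""Core containers shared across the package.

The package works with three kinds of raw inputs — a protein-protein
interaction (PPI) network, a drug-target interaction (DTI) table and
per-entity feature tables — plus the aligned index that ties them together.
All identifiers are opaque strings; species prefixes such as ``9606.`` pass
through unmodified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


def _canon_edge(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class InteractionGraph:
    """Undirected PPI graph G = (V, E) with optional edge confidences.

    ``edges`` stores each undirected edge once, as a sorted id pair; no
    self-loops are stored (propagation layers add self-loops analytically).
    ``edge_weight`` maps the canonical pair to a confidence in [0, 1]
    (STRING combined_score / 1000); missing entries default to 1.0.
    """

    node_ids: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)
    edge_weight: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodes = set(self.node_ids)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop stored in edge set: {a!r}")
            if (a, b) != _canon_edge(a, b):
                raise ValueError(f"edge not in canonical order: {(a, b)!r}")
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge endpoint not in node_ids: {(a, b)!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for e in self.edges if node in e)

    def degrees(self) -> dict[str, int]:
        deg = {v: 0 for v in self.node_ids}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def weight(self, a: str, b: str) -> float:
        return self.edge_weight.get(_canon_edge(a, b), 1.0)

    def neighbors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {v: [] for v in self.node_ids}
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    def subgraph(self, keep: Iterable[str]) -> "InteractionGraph":
        keep_set = set(keep)
        nodes = [v for v in self.node_ids if v in keep_set]
        edges = {e for e in self.edges if e[0] in keep_set and e[1] in keep_set}
        weights = {e: w for e, w in self.edge_weight.items() if e in edges}
        return InteractionGraph(nodes, edges, weights)


@dataclass
class DTIMatrix:
    """Binary drug-target interaction matrix M over drug set D and protein set P.

    Only the positive pairs are stored; every (d, p) pair not in ``positives``
    is treated as a negative (M_ij = 0).
    """

    drug_ids: list[str]
    protein_ids: list[str]
    positives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        D, P = set(self.drug_ids), set(self.protein_ids)
        bad = [pair for pair in self.positives if pair[0] not in D or pair[1] not in P]
        if bad:
            raise ValueError(f"positive pair outside D x P, e.g. {bad[0]!r}")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    def to_dense(self) -> np.ndarray:
        """Dense 0/1 matrix of shape (n_drugs, n_proteins)."""
        drug_pos = {d: i for i, d in enumerate(self.drug_ids)}
        prot_pos = {p: j for j, p in enumerate(self.protein_ids)}
        M = np.zeros((self.n_drugs, self.n_proteins), dtype=np.int8)
        for d, p in self.positives:
            M[drug_pos[d], prot_pos[p]] = 1
        return M

    def protein_interaction_counts(self) -> dict[str, int]:
        """f(p) = number of drugs known to interact with protein p."""
        counts = {p: 0 for p in self.protein_ids}
        for _, p in self.positives:
            counts[p] += 1
        return counts


@dataclass
class FeatureTable:
    """Per-entity fixed-length float vectors, row-aligned with ``entity_ids``."""

    entity_ids: list[str]
    vectors: np.ndarray  # shape (n_entities, dim)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError(f"vectors must be 2-D, got shape {self.vectors.shape}")
        if self.vectors.shape[0] != len(self.entity_ids):
            raise ValueError(
                f"{len(self.entity_ids)} ids but {self.vectors.shape[0]} vector rows"
            )
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids in feature table")

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    def row(self, entity_id: str) -> np.ndarray:
        return self.vectors[self.entity_ids.index(entity_id)]

    def reorder(self, order: Sequence[str], missing: str = "error") -> "FeatureTable":
        """Return a table with rows in the given id order.

        ``missing='zero'`` fills absent entities with zero vectors (used for
        proteins retained through the PPI graph but lacking a feature row).
        """
        lookup = {e: i for i, e in enumerate(self.entity_ids)}
        rows = np.zeros((len(order), self.dim), dtype=np.float64)
        for k, e in enumerate(order):
            i = lookup.get(e)
            if i is None:
                if missing != "zero":
                    raise KeyError(f"entity {e!r} missing from feature table")
            else:
                rows[k] = self.vectors[i]
        return FeatureTable(list(order), rows)


# An EmbeddingTable is a FeatureTable produced by a learned transformation;
# structurally identical, kept as an alias for clarity at call sites.
EmbeddingTable = FeatureTable


@dataclass
class EntityIndex:
    """Bijections id <-> 0-based position, kept separately for drugs and proteins."""

    drug_ids: list[str]
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.drug_pos: dict[str, int] = {d: i for i, d in enumerate(self.drug_ids)}
        self.protein_pos: dict[str, int] = {p: i for i, p in enumerate(self.protein_ids)}
        if len(self.drug_pos) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")
        if len(self.protein_pos) != len(self.protein_ids):
            raise ValueError("duplicate protein ids")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)


@dataclass
class PredictionSet:
    """Aligned labels l(d,p) in {0,1} and scores y(d,p) in [0,1] for pairs."""

    drug_ids: np.ndarray     # object/str array, length n
    protein_ids: np.ndarray  # object/str array, length n
    labels: np.ndarray       # int {0,1}, length n
    scores: np.ndarray       # float [0,1], length n

    def __post_init__(self) -> None:
        self.drug_ids = np.asarray(self.drug_ids, dtype=object)
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.labels = np.asarray(self.labels)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n = len(self.drug_ids)
        if not (len(self.protein_ids) == len(self.labels) == len(self.scores) == n):
            raise ValueError("prediction set arrays have mismatched lengths")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class PairScoreBatch:
    """Scores in [0,1] for an ordered list of (drug_id, protein_id) pairs."""

    pairs: list[tuple[str, str]]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.pairs) != len(self.scores):
            raise ValueError("one score per pair required")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
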