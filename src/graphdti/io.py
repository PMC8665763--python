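"""Reading, filtering and aligning the three raw inputs.

Dialects
--------
* STRING-style PPI network: header ``protein1 protein2 combined_score``,
  whitespace- or tab-separated, integer confidence on a 0-1000 scale
  (700 = high confidence).
* STITCH-style DTI table: header ``chemical protein combined_score``.
* Bare positive-pair edge list: two columns ``drug_id<TAB>protein_id``,
  no score (Yamanishi / BioSnap style).
* Feature table: column 1 = entity id, columns 2..d+1 = floats.

Confidence filtering keeps rows with ``combined_score >= threshold``
(STRING's own convention for "high confidence = 700"). Self-loop rows are
dropped at read time because the graph-convolution layers add self-loops
analytically.
"""

from __future__ import annotations

import io as _io
import logging
import os
from typing import IO, Iterable, Iterator, Union

import numpy as np

from .datatypes import DTIMatrix, EntityIndex, FeatureTable, InteractionGraph, _canon_edge

logger = logging.getLogger(__name__)

Source = Union[str, os.PathLike, IO[str]]

DEFAULT_CONFIDENCE_THRESHOLD = 700


class ParseError(ValueError):
    """A malformed row in one of the TSV dialects."""


def _open_lines(source: Source) -> Iterator[str]:
    if hasattr(source, "read"):
        yield from source  # type: ignore[misc]
    else:
        with open(source, "rt") as fh:
            yield from fh


def _rows(source: Source) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, whitespace-split fields), skipping blanks."""
    for lineno, line in enumerate(_open_lines(source), start=1):
        fields = line.split()
        if fields:
            yield lineno, fields


def read_interaction_network(
    source: Source, score_threshold: int = DEFAULT_CONFIDENCE_THRESHOLD
) -> InteractionGraph:
    """Read a STRING-dialect PPI network, keeping edges with score >= threshold.

    (a, b) and (b, a) rows collapse to a single undirected edge; when both
    directions are present with different scores the larger one is kept.
    Edge weights are stored as combined_score / 1000. Self-loop rows are
    skipped with a warning.
    """
    rows = _rows(source)
    try:
        next(rows)  # header
    except StopIteration:
        return InteractionGraph([], set(), {})
    nodes: dict[str, None] = {}
    weights: dict[tuple[str, str], float] = {}
    for lineno, fields in rows:
        if len(fields) != 3:
            raise ParseError(
                f"line {lineno}: expected 3 columns (protein1 protein2 combined_score), "
                f"got {len(fields)}"
            )
        a, b, raw = fields
        try:
            score = int(raw)
        except ValueError:
            raise ParseError(f"line {lineno}: combined_score {raw!r} is not an integer") from None
        if a == b:
            logger.warning("line %d: self-loop %r skipped", lineno, a)
            continue
        if score < score_threshold:
            continue
        nodes[a] = None
        nodes[b] = None
        edge = _canon_edge(a, b)
        w = score / 1000.0
        if edge not in weights or w > weights[edge]:
            weights[edge] = w
    return InteractionGraph(list(nodes), set(weights), weights)


def read_dti_table(source: Source, score_threshold: int | None = None) -> DTIMatrix:
    """Read a DTI table in either the STITCH (3-column, scored) dialect or the
    bare 2-column positive-pair dialect.

    For the 2-column dialect ``score_threshold`` must be None (usage error
    otherwise). Duplicate pairs are deduplicated with a warning. D and P are
    the distinct ids appearing in retained rows, in first-seen order.
    """
    rows = _rows(source)
    try:
        next(rows)  # header
    except StopIteration:
        return DTIMatrix([], [], set())
    drugs: dict[str, None] = {}
    proteins: dict[str, None] = {}
    positives: set[tuple[str, str]] = set()
    ncols: int | None = None
    for lineno, fields in rows:
        if ncols is None:
            if len(fields) not in (2, 3):
                raise ParseError(f"line {lineno}: expected 2 or 3 columns, got {len(fields)}")
            ncols = len(fields)
            if ncols == 2 and score_threshold is not None:
                raise ValueError(
                    "score_threshold given but the input is a 2-column edge list "
                    "(edge lists carry no confidence scores)"
                )
        if len(fields) != ncols:
            raise ParseError(f"line {lineno}: expected {ncols} columns, got {len(fields)}")
        if ncols == 3:
            d, p, raw = fields
            try:
                score = int(raw)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: combined_score {raw!r} is not an integer"
                ) from None
            if score_threshold is not None and score < score_threshold:
                continue
        else:
            d, p = fields
        if (d, p) in positives:
            logger.warning("line %d: duplicate pair (%s, %s) deduplicated", lineno, d, p)
            continue
        positives.add((d, p))
        drugs[d] = None
        proteins[p] = None
    return DTIMatrix(list(drugs), list(proteins), positives)


def read_feature_table(source: Source) -> FeatureTable:
    """Read a feature table: column 1 = entity id, the rest floats (no header)."""
    ids: list[str] = []
    rows: list[list[float]] = []
    dim: int | None = None
    for lineno, fields in _rows(source):
        if dim is None:
            dim = len(fields) - 1
            if dim < 0:
                raise ParseError(f"line {lineno}: empty row")
        if len(fields) - 1 != dim:
            raise ParseError(f"line {lineno}: expected {dim} feature values, got {len(fields) - 1}")
        try:
            vec = [float(x) for x in fields[1:]]
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric feature value") from None
        ids.append(fields[0])
        rows.append(vec)
    return FeatureTable(ids, np.asarray(rows, dtype=np.float64).reshape(len(ids), dim or 0))


def align_entities(
    graph: InteractionGraph,
    dti: DTIMatrix,
    protein_features: FeatureTable,
    drug_features: FeatureTable,
) -> tuple[InteractionGraph, DTIMatrix, FeatureTable, FeatureTable, EntityIndex]:
    """Restrict all resources to a consistent entity set.

    Retention rules: a protein is kept if it has at least one PPI edge *or*
    a feature row; a drug is kept only if it has a feature row. DTI positives
    are restricted to retained D x P. Feature tables are re-ordered to the
    EntityIndex order; retained proteins lacking a feature row receive zero
    vectors. Idempotent: aligning twice equals aligning once.
    """
    prot_with_edge = {v for e in graph.edges for v in e}
    prot_with_feat = set(protein_features.entity_ids)
    prot_universe: dict[str, None] = {}
    for p in list(graph.node_ids) + list(dti.protein_ids) + list(protein_features.entity_ids):
        prot_universe.setdefault(p, None)
    proteins = [p for p in prot_universe if p in prot_with_edge or p in prot_with_feat]

    drug_with_feat = set(drug_features.entity_ids)
    drug_universe: dict[str, None] = {}
    for d in list(dti.drug_ids) + list(drug_features.entity_ids):
        drug_universe.setdefault(d, None)
    drugs = [d for d in drug_universe if d in drug_with_feat]

    if not proteins or not drugs:
        raise ValueError(
            "entity alignment produced an empty dataset "
            f"({len(drugs)} drugs, {len(proteins)} proteins retained)"
        )

    keep_p, keep_d = set(proteins), set(drugs)
    positives = {(d, p) for (d, p) in dti.positives if d in keep_d and p in keep_p}
    if dti.positives and not positives:
        raise ValueError(
            "entity alignment produced an empty dataset: no DTI pair survives "
            "the entity intersection"
        )
    n_dropped = len(dti.positives) - len(positives)
    if n_dropped:
        logger.info("alignment dropped %d DTI pairs with unretained entities", n_dropped)

    graph2 = graph.subgraph(proteins)
    # graph nodes are exactly the retained proteins so propagation and the
    # DTI matrix share one index
    graph2 = InteractionGraph(proteins, graph2.edges, graph2.edge_weight)
    dti2 = DTIMatrix(drugs, proteins, positives)
    prot_feat2 = protein_features.reorder(proteins, missing="zero")
    drug_feat2 = drug_features.reorder(drugs)
    index = EntityIndex(drugs, proteins)
    return graph2, dti2, prot_feat2, drug_feat2, index


# ---------------------------------------------------------------------------
# Writers (same dialects, so synthetic data exercises the real read path)


def write_interaction_network(graph: InteractionGraph, path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b in sorted(graph.edges):
            score = int(round(graph.weight(a, b) * 1000))
            fh.write(f"{a}\t{b}\t{score}\n")


def write_dti_edge_list(dti: DTIMatrix, path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("chemical\tprotein\n")
        for d, p in sorted(dti.positives):
            fh.write(f"{d}\t{p}\n")


def write_dti_stitch(dti: DTIMatrix, path: str | os.PathLike, score: int = 900) -> None:
    with open(path, "wt") as fh:
        fh.write("chemical\tprotein\tcombined_score\n")
        for d, p in sorted(dti.positives):
            fh.write(f"{d}\t{p}\t{score}\n")


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        for e, row in zip(table.entity_ids, table.vectors):
            fh.write(e + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
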