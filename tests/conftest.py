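import io

import numpy as np
import pytest

from graphdti.datatypes import DTIMatrix, FeatureTable, InteractionGraph


@pytest.fixture
def small_graph() -> InteractionGraph:
    """Five proteins: p1-p2-p3 path plus p4 attached to p2; p5 isolated."""
    nodes = ["p1", "p2", "p3", "p4", "p5"]
    edges = {("p1", "p2"), ("p2", "p3"), ("p2", "p4")}
    return InteractionGraph(nodes, edges, {e: 1.0 for e in edges})


@pytest.fixture
def small_dti() -> DTIMatrix:
    return DTIMatrix(
        ["d1", "d2"],
        ["p1", "p2", "p3", "p4", "p5"],
        {("d1", "p1"), ("d1", "p2"), ("d2", "p2")},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def tsv(text: str) -> io.StringIO:
    """In-memory TSV from a dedented string."""
    lines = [ln.strip() for ln in text.strip().splitlines()]
    return io.StringIO("\n".join("\t".join(ln.split()) for ln in lines) + "\n")


def random_feature_table(ids, dim, rng) -> FeatureTable:
    return FeatureTable(list(ids), rng.normal(size=(len(ids), dim)))
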