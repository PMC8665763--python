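"""Trainable per-entity feature transformations and the half-twin pair scorer.

A *half-twin* network has two branches — one transforming drug features, one
transforming protein features — feeding a shared cosine-similarity scorer.
Each branch is a single affine map followed by a LeakyReLU, used purely as a
trainable dimensionality reduction so heterogeneous feature sources (e.g.
molecular vs. ontology embeddings of different widths) can be projected to a
common size and concatenated.

The pair score is ``logistic(alpha * cos(u_d, u_p) + beta)`` with learnable
scalars alpha (init 1) and beta (init 0); the cosine of a zero vector is
defined as 0, so untouched entities score 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .datatypes import EmbeddingTable, FeatureTable, PairScoreBatch


@dataclass(frozen=True)
class TransformConfig:
    input_dim: int
    output_dim: int
    activation: str = "LeakyReLU"  # or "ReLU"
    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or self.output_dim <= 0:
            raise ValueError("dims must be positive")
        if self.activation not in ("LeakyReLU", "ReLU"):
            raise ValueError(f"unknown activation {self.activation!r}")


def _activate(x: Tensor, activation: str, slope: float) -> Tensor:
    if activation == "ReLU":
        return ad.relu(x)
    return ad.leaky_relu(x, slope)


class FeatureTransform:
    """One affine map + activation; one instance per feature source."""

    def __init__(self, config: TransformConfig, rng: np.random.Generator):
        self.config = config
        self.W = ad.parameter((config.input_dim, config.output_dim), rng=rng)
        self.b = ad.parameter(np.zeros(config.output_dim))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]

    def forward(self, X: Tensor | np.ndarray) -> Tensor:
        X = ad.as_tensor(X)
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"input dim {X.shape[1]} does not match transform input_dim "
                f"{self.config.input_dim}"
            )
        return _activate(ad.matmul(X, self.W) + self.b, self.config.activation, self.config.leaky_slope)


def transform_features(
    features: FeatureTable,
    weight: np.ndarray,
    bias: np.ndarray,
    config: TransformConfig,
) -> EmbeddingTable:
    """Apply a given affine map + activation to a feature table.

    Row order is preserved; the output dimension is ``config.output_dim``.
    """
    if features.dim != config.input_dim:
        raise ValueError(
            f"feature dim {features.dim} does not match config.input_dim {config.input_dim}"
        )
    weight = np.asarray(weight, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    if weight.shape != (config.input_dim, config.output_dim):
        raise ValueError(
            f"weight shape {weight.shape} does not match "
            f"({config.input_dim}, {config.output_dim})"
        )
    z = features.vectors @ weight + bias
    if config.activation == "ReLU":
        out = np.maximum(z, 0.0)
    else:
        out = np.where(z > 0, z, config.leaky_slope * z)
    return EmbeddingTable(list(features.entity_ids), out)


def concat_features(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    """Concatenate two feature tables entity-wise, aligning rows by id."""
    ids_a, ids_b = set(a.entity_ids), set(b.entity_ids)
    if ids_a != ids_b:
        missing = sorted(ids_a.symmetric_difference(ids_b))
        raise ValueError(f"entity id sets differ; unmatched ids: {missing[:10]}")
    b_aligned = b.reorder(a.entity_ids)
    return FeatureTable(
        list(a.entity_ids), np.concatenate([a.vectors, b_aligned.vectors], axis=1)
    )


def cosine_rows(U: Tensor, V: Tensor, eps: float = 1e-12) -> Tensor:
    """Row-wise cosine similarity; zero vectors yield cosine 0."""
    num = ad.tsum(U * V, axis=1)
    nu = ad.tsum(U * U, axis=1)
    nv = ad.tsum(V * V, axis=1)
    return num / (ad.sqrt(nu * nv) + eps)


class HalfTwinScorer:
    """logistic(alpha * cos + beta) with learnable scalar alpha, beta."""

    def __init__(self, alpha: float = 1.0, beta: float = 0.0):
        self.alpha = ad.parameter(np.array(alpha))
        self.beta = ad.parameter(np.array(beta))

    def parameters(self) -> list[Tensor]:
        return [self.alpha, self.beta]

    def forward(self, U: Tensor | np.ndarray, V: Tensor | np.ndarray) -> Tensor:
        U, V = ad.as_tensor(U), ad.as_tensor(V)
        if U.shape != V.shape:
            raise ValueError(f"embedding shapes differ: {U.shape} vs {V.shape}")
        return ad.sigmoid(self.alpha * cosine_rows(U, V) + self.beta)


def score_pairs_half_twin(
    drug_emb: EmbeddingTable,
    prot_emb: EmbeddingTable,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 1.0,
    beta: float = 0.0,
) -> PairScoreBatch:
    """Score (drug, protein) pairs with the half-twin cosine scorer."""
    if drug_emb.dim != prot_emb.dim:
        raise ValueError(f"embedding dims differ: {drug_emb.dim} vs {prot_emb.dim}")
    dpos = {e: i for i, e in enumerate(drug_emb.entity_ids)}
    ppos = {e: i for i, e in enumerate(prot_emb.entity_ids)}
    missing = [d for d, _ in pairs if d not in dpos] + [p for _, p in pairs if p not in ppos]
    if missing:
        raise KeyError(f"pair entities missing from embeddings: {sorted(set(missing))[:10]}")
    di = np.asarray([dpos[d] for d, _ in pairs], dtype=np.intp)
    pi = np.asarray([ppos[p] for _, p in pairs], dtype=np.intp)
    scorer = HalfTwinScorer(alpha=alpha, beta=beta)
    scores = scorer.forward(
        Tensor(drug_emb.vectors[di]), Tensor(prot_emb.vectors[pi])
    )
    return PairScoreBatch(list(pairs), scores.data)
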