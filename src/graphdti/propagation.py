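"""Graph convolutional propagation over the PPI network.

Two message-passing layers are provided:

* **GCNConv** — symmetric degree-normalized convolution over the self-loop
  augmented adjacency: ``X' = D^(-1/2) (A + I) D^(-1/2) X Theta``.
* **GENConv** — generalized message passing that reorders activation,
  aggregation and MLP: ``x_i' = MLP(x_i + AGG({sigma(x_j + e_ji) + eps}))``
  with sum / mean / softmax (learnable temperature) / power (learnable
  exponent) aggregators. The epsilon constant (1e-7 per channel) keeps
  aggregated messages away from exact zero.

GENConv layers are wrapped in residual blocks — ``X + GEN(norm(X))`` — and
stacked; the receptive field radius of a stack equals its height. The *pruned*
variant removes the aggregation term (``x_i' = MLP(x_i + 0)``) while keeping
the MLP/normalization path and its parameter count, giving a graph-blind
model with the same capacity: the ablation that separates "more parameters"
from "uses the network".

Normalization inside the blocks standardizes each node's feature vector
(mean 0, variance 1 across channels) with a learnable per-channel affine.
Standardizing per node rather than across nodes keeps the blocks strictly
local: a perturbation outside a node's ``height``-hop neighborhood cannot
reach it through batch statistics.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .datatypes import EmbeddingTable, InteractionGraph

GEN_EPSILON = 1e-7

AggKind = Literal["sum", "mean", "softmax", "power"]


# ---------------------------------------------------------------------------
# Graph preprocessing


def build_edge_arrays(
    graph: InteractionGraph, weighted: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Directed edge lists (src, dst) covering both directions of every edge.

    With ``weighted=True`` the third element carries the scalar confidence
    e_ji per directed edge (broadcast per channel by the GEN layer);
    otherwise None (binary graph, edge feature = 0).
    """
    pos = {p: i for i, p in enumerate(graph.node_ids)}
    n = graph.n_edges
    src = np.empty(2 * n, dtype=np.intp)
    dst = np.empty(2 * n, dtype=np.intp)
    w = np.empty(2 * n, dtype=np.float64) if weighted else None
    for k, (a, b) in enumerate(sorted(graph.edges)):
        ia, ib = pos[a], pos[b]
        src[2 * k], dst[2 * k] = ia, ib
        src[2 * k + 1], dst[2 * k + 1] = ib, ia
        if w is not None:
            w[2 * k] = w[2 * k + 1] = graph.weight(a, b)
    return src, dst, w


def gcn_norm_matrix(graph: InteractionGraph, weighted: bool = False) -> sp.csr_matrix:
    """Symmetric-normalized adjacency with self-loops: D^(-1/2) (A+I) D^(-1/2)."""
    n = graph.n_nodes
    src, dst, w = build_edge_arrays(graph, weighted=weighted)
    vals = w if w is not None else np.ones(len(src))
    rows = np.concatenate([src, np.arange(n)])
    cols = np.concatenate([dst, np.arange(n)])
    data = np.concatenate([vals, np.ones(n)])  # self-loop weight 1
    A_hat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    deg = np.asarray(A_hat.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    D = sp.diags(d_inv_sqrt)
    return (D @ A_hat @ D).tocsr()


# ---------------------------------------------------------------------------
# GCNConv


class GCNLayer:
    """Symmetric-normalized graph convolution with weight matrix Theta."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.theta = ad.parameter((d_in, d_out), rng=rng)

    def parameters(self) -> list[Tensor]:
        return [self.theta]

    def forward(self, S: sp.csr_matrix, X: Tensor | np.ndarray) -> Tensor:
        X = ad.as_tensor(X)
        if X.shape[1] != self.theta.shape[0]:
            raise ValueError(
                f"input width {X.shape[1]} does not match Theta rows {self.theta.shape[0]}"
            )
        return ad.matmul(ad.spmm(S, X), self.theta)


def gcn_layer_forward(
    graph: InteractionGraph,
    X: np.ndarray,
    theta: np.ndarray,
    weighted: bool = False,
) -> np.ndarray:
    """One GCNConv step: D^(-1/2) (A+I) D^(-1/2) X Theta (rows follow graph.node_ids)."""
    X = np.asarray(X, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    if X.shape[0] != graph.n_nodes:
        raise ValueError(f"X has {X.shape[0]} rows but graph has {graph.n_nodes} nodes")
    if X.shape[1] != theta.shape[0]:
        raise ValueError(f"X width {X.shape[1]} does not match Theta rows {theta.shape[0]}")
    S = gcn_norm_matrix(graph, weighted=weighted)
    return S @ X @ theta


def gcn_dense_reference(
    graph: InteractionGraph, X: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Dense-matrix evaluation of the same update (kept for cross-checking)."""
    n = graph.n_nodes
    pos = {p: i for i, p in enumerate(graph.node_ids)}
    A = np.zeros((n, n))
    for a, b in graph.edges:
        A[pos[a], pos[b]] = A[pos[b], pos[a]] = 1.0
    A_hat = A + np.eye(n)
    d = A_hat.sum(axis=1)
    D_inv_sqrt = np.diag(1.0 / np.sqrt(d))
    return D_inv_sqrt @ A_hat @ D_inv_sqrt @ np.asarray(X, dtype=np.float64) @ theta


# ---------------------------------------------------------------------------
# GENConv


def _sigma(x: Tensor, kind: str, slope: float = 0.01) -> Tensor:
    if kind == "ReLU":
        return ad.relu(x)
    if kind == "LeakyReLU":
        return ad.leaky_relu(x, slope)
    raise ValueError(f"unknown activation {kind!r}")


class GENLayer:
    """Generalized message-passing layer: x_i' = MLP(x_i + AGG(sigma(x_j + e_ji) + eps)).

    The 2-layer MLP keeps the block width (d -> hidden -> d, ReLU inside).
    ``agg`` selects the aggregator; softmax and power carry one learnable
    scalar (temperature / exponent). The second MLP layer is zero-initialized
    so a fresh layer is the identity map inside its residual block.
    """

    def __init__(
        self,
        dim: int,
        rng: np.random.Generator,
        agg: AggKind = "softmax",
        activation: str = "ReLU",
        hidden: int | None = None,
        epsilon: float = GEN_EPSILON,
        zero_init_out: bool = True,
    ):
        if agg not in ("sum", "mean", "softmax", "power"):
            raise ValueError(f"unknown aggregation {agg!r}")
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        h = hidden or dim
        self.dim, self.agg, self.activation, self.epsilon = dim, agg, activation, epsilon
        self.W1 = ad.parameter((dim, h), rng=rng)
        self.b1 = ad.parameter(np.zeros(h))
        self.W2 = (
            ad.parameter(np.zeros((h, dim))) if zero_init_out else ad.parameter((h, dim), rng=rng)
        )
        self.b2 = ad.parameter(np.zeros(dim))
        # softmax temperature or power exponent; unused for sum/mean
        self.agg_param = ad.parameter(np.array(1.0)) if agg in ("softmax", "power") else None

    def parameters(self) -> list[Tensor]:
        ps = [self.W1, self.b1, self.W2, self.b2]
        if self.agg_param is not None:
            ps.append(self.agg_param)
        return ps

    def mlp(self, H: Tensor, norm: "NodeNorm | None" = None) -> Tensor:
        if norm is not None:
            H = norm.forward(H)
        return ad.matmul(ad.relu(ad.matmul(H, self.W1) + self.b1), self.W2) + self.b2

    def _aggregate(self, msg: Tensor, dst: np.ndarray, n: int) -> Tensor:
        if self.agg == "sum":
            return ad.segment_sum(msg, dst, n)
        counts = np.maximum(np.bincount(dst, minlength=n), 1).astype(np.float64)
        if self.agg == "mean":
            return ad.segment_sum(msg, dst, n) / Tensor(counts[:, None])
        if self.agg == "softmax":
            z = msg * self.agg_param
            shift = ad.segment_max_const(z.data, dst, n)
            shift[~np.isfinite(shift)] = 0.0
            e = ad.exp(z - ad.gather(Tensor(shift), dst))
            denom = ad.gather(ad.segment_sum(e, dst, n), dst)
            return ad.segment_sum(e / denom * msg, dst, n)
        # signed-free power mean over messages clamped positive
        msgc = ad.clip(msg, 1e-7, np.inf)
        p = self.agg_param
        powed = ad.exp(p * ad.log(msgc))
        mean_p = ad.segment_sum(powed, dst, n) / Tensor(counts[:, None])
        mean_p = ad.clip(mean_p, 1e-30, np.inf)
        return ad.exp(ad.log(mean_p) / p)

    def forward(
        self,
        X: Tensor | np.ndarray,
        src: np.ndarray | None,
        dst: np.ndarray | None,
        edge_feat: np.ndarray | None = None,
        use_graph: bool = True,
        norm: "NodeNorm | None" = None,
    ) -> Tensor:
        X = ad.as_tensor(X)
        if X.shape[1] != self.dim:
            raise ValueError(f"input width {X.shape[1]} does not match layer dim {self.dim}")
        n = X.shape[0]
        if use_graph and src is not None and len(src) > 0:
            msg_in = ad.gather(X, src)
            if edge_feat is not None:
                msg_in = msg_in + Tensor(np.asarray(edge_feat, dtype=np.float64)[:, None])
            msg = _sigma(msg_in, self.activation) + self.epsilon
            agg = self._aggregate(msg, dst, n)
            h = X + agg
        else:
            h = X  # empty neighborhood / pruned: AGG term is the zero vector
        return self.mlp(h, norm=norm)


class NodeNorm:
    """Per-node feature standardization with learnable per-channel scale/shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = ad.parameter(np.ones(dim))
        self.beta = ad.parameter(np.zeros(dim))
        self.eps = eps

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def forward(self, X: Tensor | np.ndarray) -> Tensor:
        X = ad.as_tensor(X)
        mu = ad.tmean(X, axis=1, keepdims=True)
        centered = X - mu
        var = ad.tmean(centered * centered, axis=1, keepdims=True)
        return centered / ad.sqrt(var + self.eps) * self.gamma + self.beta


class ResidualBlock:
    """Residual block: X + MLP(norm(x_i + AGG(sigma(x_j) + eps))).

    Messages are computed from the raw block input — the embeddings produced
    by the LeakyReLU transforms are nonnegative-dominated, so a ReLU message
    activation passes them nearly unchanged — and the normalization is
    applied to the MLP input, keeping the update well-scaled regardless of
    degree. Input width == output width (the residual sum must typecheck).
    """

    def __init__(
        self,
        dim: int,
        rng: np.random.Generator,
        agg: AggKind = "softmax",
        activation: str = "ReLU",
        use_graph: bool = True,
    ):
        self.dim = dim
        self.use_graph = use_graph
        self.norm = NodeNorm(dim)
        # the pruned variant never aggregates, so it carries no agg parameter
        self.gen = GENLayer(dim, rng, agg=agg, activation=activation) if use_graph else GENLayer(
            dim, rng, agg="sum", activation=activation
        )
        if not use_graph:
            self.gen.agg_param = None

    def parameters(self) -> list[Tensor]:
        return self.norm.parameters() + self.gen.parameters()

    def forward(
        self,
        X: Tensor | np.ndarray,
        src: np.ndarray | None,
        dst: np.ndarray | None,
        edge_feat: np.ndarray | None = None,
    ) -> Tensor:
        X = ad.as_tensor(X)
        if X.shape[1] != self.dim:
            raise ValueError(f"input width {X.shape[1]} does not match block width {self.dim}")
        return X + self.gen.forward(
            X, src, dst, edge_feat, use_graph=self.use_graph, norm=self.norm
        )


class PropagationStack:
    """Ordered stack of residual blocks; receptive field radius == height."""

    def __init__(
        self,
        dim: int,
        height: int = 3,
        rng: np.random.Generator | None = None,
        agg: AggKind = "softmax",
        activation: str = "ReLU",
        use_graph: bool = True,
    ):
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.use_graph = use_graph
        self.blocks = [
            ResidualBlock(dim, rng, agg=agg, activation=activation, use_graph=use_graph)
            for _ in range(height)
        ]

    @property
    def height(self) -> int:
        return len(self.blocks)

    def parameters(self) -> list[Tensor]:
        return [p for b in self.blocks for p in b.parameters()]

    def forward(
        self,
        X: Tensor | np.ndarray,
        src: np.ndarray | None = None,
        dst: np.ndarray | None = None,
        edge_feat: np.ndarray | None = None,
    ) -> Tensor:
        out = ad.as_tensor(X)
        for block in self.blocks:
            out = block.forward(out, src, dst, edge_feat)
        return out


def propagate(
    graph: InteractionGraph, X0: EmbeddingTable, stack: PropagationStack, weighted: bool = False
) -> EmbeddingTable:
    """Run the stack over the graph; rows of X0 must follow graph.node_ids."""
    if list(X0.entity_ids) != list(graph.node_ids):
        raise ValueError("embedding table rows are not aligned with graph nodes")
    src, dst, w = build_edge_arrays(graph, weighted=weighted)
    out = stack.forward(Tensor(X0.vectors), src, dst, w)
    return EmbeddingTable(list(X0.entity_ids), out.data)


def pruned_forward(X0: EmbeddingTable, stack: PropagationStack) -> EmbeddingTable:
    """Graph-free ablation: every aggregation term replaced by the zero vector."""
    out = ad.as_tensor(X0.vectors)
    for block in stack.blocks:
        out = out + block.gen.forward(out, None, None, use_graph=False, norm=block.norm)
    return EmbeddingTable(list(X0.entity_ids), out.data)


def parameter_count(params: list[Tensor]) -> int:
    return int(sum(p.data.size for p in params))
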