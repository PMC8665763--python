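"""GCN/GEN layers, residual blocks, locality and the pruned ablation."""

import numpy as np
import pytest

import networkx as nx

from graphdti.autodiff import Tensor
from graphdti.datatypes import EmbeddingTable, InteractionGraph, _canon_edge
from graphdti.propagation import (
    GCNLayer,
    GENLayer,
    NodeNorm,
    PropagationStack,
    ResidualBlock,
    build_edge_arrays,
    gcn_dense_reference,
    gcn_layer_forward,
    gcn_norm_matrix,
    parameter_count,
    propagate,
    pruned_forward,
)


def _random_graph(n, p, seed):
    g = nx.gnp_random_graph(n, p, seed=seed)
    ids = [f"n{i:03d}" for i in range(n)]
    edges = {_canon_edge(ids[a], ids[b]) for a, b in g.edges()}
    return InteractionGraph(ids, edges, {e: 1.0 for e in edges})


def _path_graph(n):
    ids = [f"v{i}" for i in range(n)]
    edges = {_canon_edge(ids[i], ids[i + 1]) for i in range(n - 1)}
    return InteractionGraph(ids, edges, {e: 1.0 for e in edges})


def _identity_gen(dim, agg="sum", activation="ReLU", epsilon=1e-7):
    """GEN layer whose 2-layer MLP is the identity on nonnegative input."""
    layer = GENLayer(dim, np.random.default_rng(0), agg=agg, activation=activation,
                     epsilon=epsilon, zero_init_out=False)
    layer.W1.data = np.eye(dim)
    layer.b1.data = np.zeros(dim)
    layer.W2.data = np.eye(dim)
    layer.b2.data = np.zeros(dim)
    return layer


class TestGCN:
    def test_edgeless_graph_collapses_to_plain_linear_map(self, rng):
        g = InteractionGraph(["a", "b", "c"], set(), {})
        X = rng.normal(size=(3, 4))
        theta = rng.normal(size=(4, 2))
        np.testing.assert_allclose(gcn_layer_forward(g, X, theta), X @ theta, atol=1e-12)

    def test_two_node_average(self):
        g = InteractionGraph(["a", "b"], {("a", "b")}, {("a", "b"): 1.0})
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = gcn_layer_forward(g, X, np.eye(2))
        np.testing.assert_allclose(out, [[0.5, 0.5], [0.5, 0.5]], atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_sparse_matches_dense_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        g = _random_graph(n, 0.15, seed)
        X = rng.normal(size=(n, 6))
        theta = rng.normal(size=(6, 4))
        sparse = gcn_layer_forward(g, X, theta)
        dense = gcn_dense_reference(g, X, theta)
        assert np.abs(sparse - dense).max() < 1e-5

    def test_gcn_layer_class_uses_same_operator(self, rng):
        g = _random_graph(12, 0.3, 5)
        X = rng.normal(size=(12, 3))
        layer = GCNLayer(3, 2, rng)
        out = layer.forward(gcn_norm_matrix(g), Tensor(X))
        np.testing.assert_allclose(out.data, gcn_layer_forward(g, X, layer.theta.data), atol=1e-12)


class TestGEN:
    def test_isolated_node_identity_mlp_returns_input(self):
        layer = _identity_gen(3)
        X = np.array([[0.5, 1.0, 2.0]])
        out = layer.forward(Tensor(X), None, None, use_graph=True)
        np.testing.assert_allclose(out.data, X, atol=1e-12)

    def test_single_neighbor_sum_aggregation(self):
        # node 0 receives from node 1: x0' = x0 + ReLU(x1) + eps
        layer = _identity_gen(2, agg="sum", epsilon=1e-7)
        X = np.array([[1.0, 2.0], [3.0, -1.0]])
        src = np.array([1])
        dst = np.array([0])
        out = layer.forward(Tensor(X), src, dst)
        want0 = X[0] + np.maximum(X[1], 0) + 1e-7  # x0 + ReLU(x1) + eps, all >= 0
        np.testing.assert_allclose(out.data[0], want0, atol=1e-12)
        # node 1 has no in-edges: the MLP (identity on nonnegative input) sees x1 alone
        np.testing.assert_allclose(out.data[1], np.maximum(X[1], 0), atol=1e-12)

    def test_softmax_equals_mean_for_identical_messages(self):
        soft = _identity_gen(2, agg="softmax")
        mean = _identity_gen(2, agg="mean")
        X = np.array([[0.2, 0.4], [1.0, 2.0], [1.0, 2.0]])
        src = np.array([1, 2])
        dst = np.array([0, 0])
        np.testing.assert_allclose(
            soft.forward(Tensor(X), src, dst).data,
            mean.forward(Tensor(X), src, dst).data,
            atol=1e-9,
        )

    def test_unknown_aggregation_rejected(self):
        with pytest.raises(ValueError, match="aggregation"):
            GENLayer(2, np.random.default_rng(0), agg="median")

    @pytest.mark.parametrize("agg", ["sum", "mean", "softmax", "power"])
    def test_gradients_flow_through_aggregators(self, agg, rng):
        layer = GENLayer(3, rng, agg=agg, zero_init_out=False)
        g = _random_graph(8, 0.4, 2)
        src, dst, _ = build_edge_arrays(g)
        X = Tensor(np.abs(rng.normal(size=(8, 3))) + 0.1, requires_grad=True)
        layer.forward(X, src, dst).sum().backward()
        assert X.grad is not None and np.isfinite(X.grad).all()
        assert np.abs(X.grad).max() > 0


class TestResidualBlock:
    def test_zero_mlp_is_identity(self, rng):
        block = ResidualBlock(4, rng)  # W2 zero-initialized
        g = _random_graph(6, 0.5, 3)
        src, dst, _ = build_edge_arrays(g)
        X = rng.normal(size=(6, 4))
        out = block.forward(Tensor(X), src, dst)
        np.testing.assert_allclose(out.data, X, atol=1e-12)

    def test_two_identity_blocks_equal_one(self, rng):
        g = _random_graph(6, 0.5, 3)
        src, dst, _ = build_edge_arrays(g)
        X = rng.normal(size=(6, 4))
        b1, b2 = ResidualBlock(4, rng), ResidualBlock(4, rng)
        once = b1.forward(Tensor(X), src, dst)
        twice = b2.forward(once, src, dst)
        np.testing.assert_allclose(twice.data, X, atol=1e-12)

    def test_node_norm_standardizes_constant_rows_to_zero(self):
        norm = NodeNorm(4)
        X = np.full((3, 4), 7.0)  # constant feature vector per node
        out = norm.forward(Tensor(X))
        np.testing.assert_allclose(out.data, np.zeros((3, 4)), atol=1e-6)

    def test_width_mismatch_raises(self, rng):
        block = ResidualBlock(4, rng)
        with pytest.raises(ValueError, match="width"):
            block.forward(Tensor(rng.normal(size=(3, 5))), None, None)


class TestPropagationStack:
    def _stack_and_graph(self, height, n=8, seed=0):
        rng = np.random.default_rng(seed)
        g = _path_graph(n)
        src, dst, _ = build_edge_arrays(g)
        # LeakyReLU messages keep the receptive field exact (ReLU may gate a
        # perturbation to zero for unlucky parameter draws)
        stack = PropagationStack(3, height=height, rng=rng, activation="LeakyReLU")
        for b in stack.blocks:  # activate the graph path with random weights
            b.gen.W2.data = rng.normal(size=b.gen.W2.shape) * 0.3
            b.gen.b1.data = np.full(b.gen.b1.shape, 1.0)  # keep MLP hidden units active
        return g, src, dst, stack

    def test_height_zero_is_identity(self, rng):
        g = _path_graph(5)
        stack = PropagationStack(3, height=0, rng=rng)
        X0 = EmbeddingTable(list(g.node_ids), rng.normal(size=(5, 3)))
        out = propagate(g, X0, stack)
        np.testing.assert_array_equal(out.vectors, X0.vectors)

    @pytest.mark.parametrize("distance,expect_change", [(3, True), (4, False)])
    def test_receptive_field_radius_equals_height(self, distance, expect_change):
        g, src, dst, stack = self._stack_and_graph(height=3)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        probe = 0  # path graph: node i is at distance i from node 0
        base = stack.forward(Tensor(X), src, dst).data[probe]
        X2 = X.copy()
        X2[distance] += 1.0
        pert = stack.forward(Tensor(X2), src, dst).data[probe]
        changed = np.abs(pert - base).max() > 0
        assert changed == expect_change
        if not expect_change:
            np.testing.assert_array_equal(pert, base)  # exactly zero difference

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        for seed in range(5):
            n = int(rng.integers(5, 31))
            g = _random_graph(n, 0.3, seed)
            stack = PropagationStack(4, height=2, rng=np.random.default_rng(seed))
            for b in stack.blocks:
                b.gen.W2.data = np.random.default_rng(seed + 1).normal(size=b.gen.W2.shape)
            X = rng.normal(size=(n, 4))
            src, dst, _ = build_edge_arrays(g)
            out = stack.forward(Tensor(X), src, dst).data

            perm = rng.permutation(n)
            ids_perm = [g.node_ids[i] for i in perm]
            g_perm = InteractionGraph(
                ids_perm, set(g.edges), dict(g.edge_weight)
            )
            src_p, dst_p, _ = build_edge_arrays(g_perm)
            X_perm = X[perm]
            out_perm = stack.forward(Tensor(X_perm), src_p, dst_p).data
            np.testing.assert_allclose(out_perm, out[perm], atol=1e-9)

    def test_parameter_count_independent_of_graph_size(self):
        s_small = PropagationStack(4, height=3, rng=np.random.default_rng(0))
        s_large = PropagationStack(4, height=3, rng=np.random.default_rng(1))
        n_small = parameter_count(s_small.parameters())
        # same config, any graph: weight sharing means the count is fixed
        assert n_small == parameter_count(s_large.parameters())


class TestPrunedAblation:
    def test_output_independent_of_graph(self, rng):
        stack = PropagationStack(3, height=2, rng=rng, use_graph=False)
        for b in stack.blocks:
            b.gen.W2.data = rng.normal(size=b.gen.W2.shape)
        X0 = EmbeddingTable([f"v{i}" for i in range(6)], rng.normal(size=(6, 3)))
        g1 = _random_graph(6, 0.8, 1)
        g2 = _random_graph(6, 0.1, 2)
        ids = list(X0.entity_ids)
        g1 = InteractionGraph(ids, {(_canon_edge(ids[a], ids[b])) for a, b in [(0, 1), (2, 3)]})
        g2 = InteractionGraph(ids, {(_canon_edge(ids[a], ids[b])) for a, b in [(0, 5), (1, 4), (2, 5)]})
        out1 = propagate(g1, X0, stack)
        out2 = propagate(g2, X0, stack)
        np.testing.assert_array_equal(out1.vectors, out2.vectors)

    def test_pruned_equals_propagate_on_edgeless_graph(self, rng):
        stack = PropagationStack(3, height=2, rng=rng, use_graph=True, agg="sum")
        for b in stack.blocks:
            b.gen.W2.data = rng.normal(size=b.gen.W2.shape)
            b.gen.epsilon = 1e-30  # epsilon term only matters when edges exist
        ids = [f"v{i}" for i in range(5)]
        g = InteractionGraph(ids, set(), {})
        X0 = EmbeddingTable(ids, rng.normal(size=(5, 3)))
        via_graph = propagate(g, X0, stack)
        via_pruned = pruned_forward(X0, stack)
        np.testing.assert_allclose(via_graph.vectors, via_pruned.vectors, atol=1e-12)

    def test_parameter_counts_match_mlp_and_norm_path(self):
        full = PropagationStack(4, height=3, rng=np.random.default_rng(0), agg="softmax")
        pruned = PropagationStack(4, height=3, rng=np.random.default_rng(0), use_graph=False)
        n_full = parameter_count(full.parameters())
        n_pruned = parameter_count(pruned.parameters())
        # the full stack carries exactly one extra scalar (softmax temperature) per block
        assert n_full - n_pruned == full.height
        mlp_norm = sum(
            parameter_count(b.norm.parameters())
            + parameter_count([b.gen.W1, b.gen.b1, b.gen.W2, b.gen.b2])
            for b in full.blocks
        )
        assert n_pruned == mlp_norm


def test_propagate_requires_alignment(rng):
    g = _path_graph(4)
    stack = PropagationStack(2, height=1, rng=rng)
    X0 = EmbeddingTable(["x", "y", "z", "w"], rng.normal(size=(4, 2)))
    with pytest.raises(ValueError, match="aligned"):
        propagate(g, X0, stack)
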