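"""Layer math against dense brute-force oracles and hand computations."""

import numpy as np
import pytest
from scipy import sparse as sp

from monet.data_io import GeneNetwork
from monet.gnn_core import (MonetModel, concat_embeddings,
                            gat_attention_weights, gat_layer_forward,
                            gcn_layer_forward, monet_forward,
                            normalize_adjacency, self_loop_edge_index)
from monet.data_io import AttributedGraphDataset, LabelCatalog, OmicsFeatureTable, assemble_dataset

from conftest import make_network, random_graph


# ---------------------------------------------------------------- oracles

def dense_gcn_oracle(adj: np.ndarray, H: np.ndarray, W: np.ndarray,
                     sigma=lambda x: np.maximum(x, 0)):
    """Direct dense evaluation: sigma(D̃^{-1/2}(A+I)D̃^{-1/2} H W)."""
    a_tilde = adj + np.eye(adj.shape[0])
    d = a_tilde.sum(axis=1)
    norm = a_tilde / np.sqrt(np.outer(d, d))
    return sigma(norm @ H @ W)


def dense_gat_oracle(adj_self: np.ndarray, h: np.ndarray, heads,
                     slope=0.2, sigma=lambda x: x):
    """Brute force over all (i, j): per-head attention logits from the
    concatenated transformed features, softmax per neighbourhood, mean over
    heads, nonlinearity last."""
    n = h.shape[0]
    f_out = heads[0][0].shape[1]
    acc = np.zeros((n, f_out))
    for W, a in heads:
        Wh = h @ W
        a = np.asarray(a).ravel()
        for i in range(n):
            nbrs = [j for j in range(n) if adj_self[i, j]]
            e = []
            for j in nbrs:
                z = a @ np.concatenate([Wh[i], Wh[j]])
                e.append(z if z > 0 else slope * z)
            e = np.array(e)
            alpha = np.exp(e - e.max())
            alpha /= alpha.sum()
            for t, j in enumerate(nbrs):
                acc[i] += alpha[t] * Wh[j]
    return sigma(acc / len(heads))


# ------------------------------------------------------ normalize_adjacency

class TestNormalizeAdjacency:
    def test_single_isolated_node(self):
        net = make_network(["A"], [])
        np.testing.assert_allclose(normalize_adjacency(net).matrix.toarray(),
                                   [[1.0]])

    def test_two_nodes_one_edge_all_half(self):
        net = make_network("AB", [("A", "B")])
        np.testing.assert_allclose(normalize_adjacency(net).matrix.toarray(),
                                   np.full((2, 2), 0.5))

    def test_path_graph_hand_values(self, path_network):
        m = normalize_adjacency(path_network).matrix.toarray()
        s6 = 1 / np.sqrt(6)
        expected = np.array([[0.5, s6, 0.0],
                             [s6, 1 / 3, s6],
                             [0.0, s6, 0.5]])
        np.testing.assert_allclose(m, expected, atol=1e-15)

    def test_symmetric_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            net, _ = random_graph(rng, 12, 0.3)
            m = normalize_adjacency(net).matrix.toarray()
            np.testing.assert_allclose(m, m.T, atol=1e-15)
            assert (np.diag(m) > 0).all()

    def test_k_regular_graph_equals_scaled_adjacency(self):
        # a 4-cycle is 2-regular: every entry of the normalized matrix is
        # Ã_ij / (k+1)
        net = make_network("ABCD", [("A", "B"), ("B", "C"), ("C", "D"),
                                    ("D", "A")])
        m = normalize_adjacency(net).matrix.toarray()
        a_tilde = net.adjacency().toarray() + np.eye(4)
        np.testing.assert_allclose(m, a_tilde / 3.0, atol=1e-15)


# ------------------------------------------------------------- gcn layer

class TestGCNLayer:
    def test_isolated_node_passthrough(self):
        net = make_network(["A"], [])
        out = gcn_layer_forward(normalize_adjacency(net),
                                np.array([[1.0, 0.0]]), np.eye(2), "relu")
        np.testing.assert_allclose(out, [[1.0, 0.0]])

    def test_two_node_averaging(self):
        net = make_network("AB", [("A", "B")])
        out = gcn_layer_forward(normalize_adjacency(net),
                                np.array([[1.0], [0.0]]), np.array([[1.0]]),
                                "relu")
        np.testing.assert_allclose(out, [[0.5], [0.5]])

    def test_negative_preactivation_clipped(self):
        net = make_network("AB", [("A", "B")])
        out = gcn_layer_forward(normalize_adjacency(net),
                                np.array([[1.0], [0.0]]), np.array([[-1.0]]),
                                "relu")
        np.testing.assert_allclose(out, [[0.0], [0.0]])

    def test_dimension_mismatch_errors(self, path_network):
        with pytest.raises(ValueError):
            gcn_layer_forward(normalize_adjacency(path_network),
                              np.ones((3, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError):
            gcn_layer_forward(normalize_adjacency(path_network),
                              np.ones((4, 2)), np.ones((2, 2)))

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(2, 20))
            net, adj = random_graph(rng, n, 0.35)
            H = rng.standard_normal((n, 5))
            W = rng.standard_normal((5, 4))
            ours = gcn_layer_forward(normalize_adjacency(net), H, W, "relu")
            np.testing.assert_allclose(ours, dense_gcn_oracle(adj, H, W),
                                       atol=1e-6)


# ------------------------------------------------------------- gat layer

class TestGATAttention:
    def test_self_only_neighbourhood_gives_one(self):
        h = np.array([[1.0, 2.0]])
        alpha = gat_attention_weights(h, np.eye(2), np.ones(4), {0: [0]})
        assert alpha[(0, 0)] == pytest.approx(1.0)

    def test_identical_neighbours_split_evenly(self):
        h = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        rng = np.random.default_rng(0)
        alpha = gat_attention_weights(h, rng.standard_normal((2, 2)),
                                      rng.standard_normal(4), {0: [1, 2]})
        assert alpha[(0, 1)] == pytest.approx(alpha[(0, 2)]) == pytest.approx(0.5)

    def test_zero_attention_vector_gives_exact_uniform(self):
        rng = np.random.default_rng(1)
        h = rng.standard_normal((4, 3))
        alpha = gat_attention_weights(h, rng.standard_normal((3, 2)),
                                      np.zeros(4), {0: [0, 1, 2, 3]})
        for j in range(4):
            assert alpha[(0, j)] == 0.25

    def test_weights_sum_to_one_per_node(self):
        rng = np.random.default_rng(2)
        net, adj = random_graph(rng, 10, 0.4)
        adj_self = adj + np.eye(10, dtype=int)
        nbrs = {i: list(np.flatnonzero(adj_self[i])) for i in range(10)}
        alpha = gat_attention_weights(rng.standard_normal((10, 3)),
                                      rng.standard_normal((3, 2)),
                                      rng.standard_normal(4), nbrs)
        for i in range(10):
            total = sum(alpha[(i, j)] for j in nbrs[i])
            assert total == pytest.approx(1.0, abs=1e-8)
        assert all(v > 0 for v in alpha.values())

    def test_empty_neighbourhood_errors(self):
        with pytest.raises(ValueError, match="empty"):
            gat_attention_weights(np.ones((1, 2)), np.eye(2), np.ones(4),
                                  {0: []})


class TestGATLayer:
    def test_single_neighbour_no_self_copies_neighbour(self):
        # node 0's only neighbour is node 1: alpha = 1, output = W h_1 = h_1
        h = np.array([[5.0, -1.0], [2.0, 3.0]])
        edge_index = (np.array([0, 1]), np.array([1, 1]))
        out = gat_layer_forward(h, [(np.eye(2), np.ones(4))], edge_index,
                                aggregation="mean", sigma="identity")
        np.testing.assert_allclose(out[0], h[1])

    def test_duplicate_heads_mean_equals_single_head(self):
        rng = np.random.default_rng(3)
        net, adj = random_graph(rng, 8, 0.4)
        h = rng.standard_normal((8, 3))
        W, a = rng.standard_normal((3, 4)), rng.standard_normal(8)
        ei = self_loop_edge_index(net)
        one = gat_layer_forward(h, [(W, a)], ei, "mean")
        two = gat_layer_forward(h, [(W, a), (W, a)], ei, "mean")
        np.testing.assert_allclose(one, two, atol=1e-12)

    def test_three_node_star_matches_dense_oracle(self):
        net = make_network("ABC", [("A", "B"), ("A", "C")])
        adj_self = net.adjacency().toarray() + np.eye(3)
        rng = np.random.default_rng(4)
        h = rng.standard_normal((3, 3))
        heads = [(rng.standard_normal((3, 2)), rng.standard_normal(4))
                 for _ in range(2)]
        ours = gat_layer_forward(h, heads, self_loop_edge_index(net), "mean")
        np.testing.assert_allclose(ours, dense_gat_oracle(adj_self, h, heads),
                                   atol=1e-6)

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(2, 20))
            net, adj = random_graph(rng, n, 0.35)
            h = rng.standard_normal((n, 4))
            k = int(rng.integers(1, 4))
            heads = [(rng.standard_normal((4, 3)), rng.standard_normal(6))
                     for _ in range(k)]
            ours = gat_layer_forward(h, heads, self_loop_edge_index(net),
                                     "mean", sigma="elu")
            oracle = dense_gat_oracle(
                adj + np.eye(n), h, heads,
                sigma=lambda x: np.where(x > 0, x, np.expm1(x)))
            np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_concat_aggregation_stacks_heads(self):
        rng = np.random.default_rng(6)
        net, _ = random_graph(rng, 6, 0.5)
        h = rng.standard_normal((6, 3))
        ei = self_loop_edge_index(net)
        heads = [(rng.standard_normal((3, 2)), rng.standard_normal(4))
                 for _ in range(3)]
        out = gat_layer_forward(h, heads, ei, "concat")
        assert out.shape == (6, 6)
        for k, head in enumerate(heads):
            single = gat_layer_forward(h, [head], ei, "mean")
            np.testing.assert_allclose(out[:, 2 * k:2 * k + 2], single,
                                       atol=1e-12)

    def test_mean_with_mixed_dims_errors(self):
        net = make_network("AB", [("A", "B")])
        ei = self_loop_edge_index(net)
        heads = [(np.ones((2, 2)), np.ones(4)), (np.ones((2, 3)), np.ones(6))]
        with pytest.raises(ValueError, match="equal per-head"):
            gat_layer_forward(np.ones((2, 2)), heads, ei, "mean")

    def test_no_heads_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            gat_layer_forward(np.ones((2, 2)), [],
                              (np.array([0, 1]), np.array([0, 1])))


# -------------------------------------------------------------- concat

class TestConcatEmbeddings:
    def test_column_order_gcn_first(self):
        out = concat_embeddings(np.array([[1.0, 2.0]]), np.array([[3.0]]))
        np.testing.assert_array_equal(out, [[1.0, 2.0, 3.0]])

    def test_full_width(self):
        out = concat_embeddings(np.zeros((5, 16)), np.zeros((5, 16)))
        assert out.shape == (5, 32)

    def test_row_mismatch_errors(self):
        with pytest.raises(ValueError):
            concat_embeddings(np.zeros((2, 4)), np.zeros((3, 4)))


# ---------------------------------------------------------- full forward

def tiny_dataset(rng, n=10):
    net, _ = random_graph(rng, n, 0.4)
    features = rng.standard_normal((n, 6))
    table = OmicsFeatureTable(genes=net.nodes,
                              columns=tuple(f"MF_C{j}" for j in range(6)),
                              values=features)
    cat = LabelCatalog(positives=frozenset(net.nodes[:2]),
                       negatives=frozenset(net.nodes[2:4]))
    return assemble_dataset(net, table, cat)


class TestMonetForward:
    def test_zero_weights_give_half_everywhere(self):
        rng = np.random.default_rng(8)
        ds = tiny_dataset(rng)
        model = MonetModel(d_in=6, gcn_dims=(8, 4), gat_hidden_dim=4,
                           gat_heads_hidden=2, gat_out_dim=4, mlp_hidden=3,
                           seed=0)
        for p in model.parameters():
            p.data[:] = 0.0
        np.testing.assert_allclose(monet_forward(ds, model), 0.5)

    def test_inference_is_deterministic(self):
        rng = np.random.default_rng(9)
        ds = tiny_dataset(rng)
        model = MonetModel(d_in=6, gcn_dims=(8, 4), gat_hidden_dim=4,
                           gat_heads_hidden=2, gat_out_dim=4, mlp_hidden=3,
                           seed=1)
        np.testing.assert_array_equal(monet_forward(ds, model),
                                      monet_forward(ds, model))

    def test_matches_stepwise_composition(self):
        """The full forward equals the external composition of the pieces."""
        rng = np.random.default_rng(10)
        ds = tiny_dataset(rng)
        model = MonetModel(d_in=6, gcn_dims=(8, 4), gat_hidden_dim=4,
                           gat_heads_hidden=2, gat_out_dim=4, mlp_hidden=3,
                           seed=2)
        adj = normalize_adjacency(ds.network)
        ei = self_loop_edge_index(ds.network)
        h = ds.features
        Ws = [w.data for w in model.gcn_weights]
        g = gcn_layer_forward(adj, h, Ws[0], "relu")
        g = gcn_layer_forward(adj, g, Ws[1], "identity")
        hidden_heads = [(W.data, np.vstack([a1.data, a2.data]).ravel())
                        for W, a1, a2 in model.gat_hidden_heads]
        t = gat_layer_forward(h, hidden_heads, ei, "concat", "elu")
        W, a1, a2 = model.gat_out_head
        out_head = [(W.data, np.vstack([a1.data, a2.data]).ravel())]
        t = gat_layer_forward(t, out_head, ei, "mean", "identity")
        z = concat_embeddings(g, t)
        hid = np.maximum(z @ model.mlp_w1.data + model.mlp_b1.data, 0)
        logits = hid @ model.mlp_w2.data + model.mlp_b2.data
        expected = 1 / (1 + np.exp(-logits.ravel()))
        np.testing.assert_allclose(monet_forward(ds, model), expected,
                                   atol=1e-6)

    def test_permutation_equivariance(self):
        """Relabeling nodes permutes the output probabilities identically."""
        rng = np.random.default_rng(11)
        n = 10
        net, adj = random_graph(rng, n, 0.4)
        feats = rng.standard_normal((n, 5))
        perm = rng.permutation(n)
        # rename node i -> position perm[i] in a fresh sorted universe
        new_names = [f"m{perm[i]:02d}" for i in range(n)]
        mapping = dict(zip(net.nodes, new_names))
        net2 = GeneNetwork(
            nodes=tuple(sorted(new_names)),
            edges=frozenset(frozenset(mapping[g] for g in e)
                            for e in net.edges))
        feats2 = np.empty_like(feats)
        feats2[perm] = feats

        def dataset(network, features):
            table = OmicsFeatureTable(
                genes=network.nodes,
                columns=tuple(f"MF_C{j}" for j in range(5)),
                values=features)
            cat = LabelCatalog(positives=frozenset(network.nodes[:1]),
                               negatives=frozenset(network.nodes[1:2]))
            return assemble_dataset(network, table, cat)

        model = MonetModel(d_in=5, gcn_dims=(6, 4), gat_hidden_dim=4,
                           gat_heads_hidden=2, gat_out_dim=4, mlp_hidden=3,
                           seed=3)
        p1 = monet_forward(dataset(net, feats), model)
        p2 = monet_forward(dataset(net2, feats2), model)
        np.testing.assert_allclose(p2[perm], p1, atol=1e-10)

    def test_checkpoint_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(12)
        ds = tiny_dataset(rng)
        model = MonetModel(d_in=6, gcn_dims=(8, 4), gat_hidden_dim=4,
                           gat_heads_hidden=2, gat_out_dim=4, mlp_hidden=3,
                           seed=4)
        p = tmp_path / "ckpt.npz"
        model.save(p)
        clone = MonetModel.load(p, gcn_dims=(8, 4), gat_hidden_dim=4,
                                gat_heads_hidden=2, gat_out_dim=4,
                                mlp_hidden=3)
        np.testing.assert_array_equal(monet_forward(ds, model),
                                      monet_forward(ds, clone))
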