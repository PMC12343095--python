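"""Graph layers against brute-force dense/loop oracles."""

import numpy as np
import pytest

from combosyn.encoders import (
    AttFpParams,
    GatLayerParams,
    GcnLayerParams,
    attfp_encode,
    gat_attention,
    gat_layer,
    gcn_layer,
    global_pool,
    normalized_adjacency,
)
from combosyn.nn import Tensor


def random_graph(rng, n):
    A = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
    A = A + A.T
    return A


def sigmoid(x):
    return 1 / (1 + np.exp(-x))


# --------------------------------------------------------------------------
# GCN
# --------------------------------------------------------------------------


class TestGcn:
    def test_single_node_identity(self):
        p = GcnLayerParams(W=Tensor(np.eye(3)), activation="identity")
        H = Tensor(np.array([[1.0, 2.0, 3.0]]))
        out = gcn_layer(H, np.zeros((1, 1)), p)
        assert np.allclose(out.data, H.data)

    def test_two_node_path_hand_computed(self):
        # A+I = [[1,1],[1,1]], degrees 2 -> norm = ones/2
        p = GcnLayerParams(W=Tensor(np.eye(2)), activation="identity")
        H = Tensor(np.eye(2))
        out = gcn_layer(H, np.array([[0.0, 1.0], [1.0, 0.0]]), p)
        assert np.allclose(out.data, np.full((2, 2), 0.5))

    def test_matches_dense_oracle_on_random_graphs(self):
        """sigma(D^-1/2 (A+I) D^-1/2 H W) via explicit dense products."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(1, 7)
            A = random_graph(rng, n)
            H = rng.normal(size=(n, 4))
            W = rng.normal(size=(4, 3))
            p = GcnLayerParams(W=Tensor(W), activation="relu")
            got = gcn_layer(Tensor(H), A, p).data
            A_hat = A + np.eye(n)
            D = np.diag(A_hat.sum(1))
            D_inv_sqrt = np.diag(1 / np.sqrt(np.diag(D)))
            expected = np.maximum(D_inv_sqrt @ A_hat @ D_inv_sqrt @ H @ W, 0)
            assert np.allclose(got, expected, atol=1e-6)

    def test_zero_weights_give_zero_output(self):
        p = GcnLayerParams(W=Tensor(np.zeros((3, 2))), activation="identity")
        out = gcn_layer(Tensor(np.random.default_rng(0).normal(size=(4, 3))),
                        random_graph(np.random.default_rng(1), 4), p)
        assert np.all(out.data == 0)

    def test_shape_mismatch_raises(self):
        p = GcnLayerParams(W=Tensor(np.eye(3)))
        with pytest.raises(ValueError, match="fan-in"):
            gcn_layer(Tensor(np.ones((2, 5))), np.zeros((2, 2)), p)


# --------------------------------------------------------------------------
# GAT
# --------------------------------------------------------------------------


def gat_params(rng, d_in, d_out, heads=1, activation="identity", combine="concat"):
    return GatLayerParams.init(rng, d_in, d_out, heads=heads,
                               activation=activation, combine=combine)


class TestGatAttention:
    def test_isolated_node_attends_to_itself(self):
        p = gat_params(np.random.default_rng(0), 2, 2)
        alpha = gat_attention(Tensor(np.ones((1, 2))), np.zeros((1, 1)), p)
        assert alpha.data[0, 0] == pytest.approx(1.0)

    def test_identical_neighbors_share_attention(self):
        # node 0 linked to nodes 1 and 2 with identical features
        A = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], float)
        H = Tensor(np.array([[5.0, -1.0], [2.0, 2.0], [2.0, 2.0]]))
        p = gat_params(np.random.default_rng(3), 2, 2)
        alpha = gat_attention(H, A, p).data
        assert alpha[0, 1] == pytest.approx(alpha[0, 2])

    def test_hand_set_logits_softmax(self):
        """e = (1, 2) over a 2-neighborhood -> softmax(1, 2)."""
        p = GatLayerParams(
            Ws=[Tensor(np.eye(1))], a_src=[Tensor(np.zeros((1, 1)))],
            a_dst=[Tensor(np.ones((1, 1)))], activation="identity")
        # features chosen so destination scores are 1 and 2, masked to both
        H = Tensor(np.array([[1.0], [2.0]]))
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        alpha = gat_attention(H, A, p).data
        e = np.exp([1.0, 2.0])
        assert alpha[0] == pytest.approx(e / e.sum(), abs=1e-4)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = rng.integers(1, 7)
            p = gat_params(rng, 3, 4)
            alpha = gat_attention(Tensor(rng.normal(size=(n, 3))),
                                  random_graph(rng, n), p)
            assert np.allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)


class TestGatLayer:
    def test_single_node_is_linear_map(self):
        rng = np.random.default_rng(0)
        p = gat_params(rng, 3, 2)
        h = rng.normal(size=(1, 3))
        out = gat_layer(Tensor(h), np.zeros((1, 1)), p)
        assert np.allclose(out.data, h @ p.Ws[0].data)

    def test_matches_per_node_loop_oracle(self):
        """Explicit double loop over nodes and neighbors (incl. self-loop)."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(1, 7)
            A = random_graph(rng, n)
            H = rng.normal(size=(n, 3))
            p = gat_params(rng, 3, 2)
            got = gat_layer(Tensor(H), A, p).data
            W, a_s, a_d = p.Ws[0].data, p.a_src[0].data, p.a_dst[0].data
            Wh = H @ W
            expected = np.zeros((n, 2))
            for u in range(n):
                nbrs = [w for w in range(n) if A[u, w] or w == u]
                e = np.array([
                    (Wh[u] @ a_s + Wh[w] @ a_d).item() for w in nbrs])
                e = np.where(e > 0, e, 0.2 * e)
                alpha = np.exp(e - e.max())
                alpha /= alpha.sum()
                expected[u] = sum(al * Wh[w] for al, w in zip(alpha, nbrs))
            assert np.allclose(got, expected, atol=1e-6)

    def test_uniform_features_give_identical_rows(self):
        p = gat_params(np.random.default_rng(1), 3, 4, heads=2)
        H = Tensor(np.tile([[1.0, 2.0, 0.5]], (4, 1)))
        A = np.ones((4, 4)) - np.eye(4)
        out = gat_layer(H, A, p).data
        assert np.allclose(out, out[0])

    def test_multihead_concat_and_mean_widths(self):
        rng = np.random.default_rng(4)
        H, A = Tensor(rng.normal(size=(3, 5))), random_graph(rng, 3)
        assert gat_layer(H, A, gat_params(rng, 5, 4, heads=3)).shape == (3, 12)
        assert gat_layer(H, A, gat_params(rng, 5, 4, heads=3, combine="mean")).shape == (3, 4)

    def test_node_relabeling_permutes_rows(self):
        rng = np.random.default_rng(9)
        n = 5
        A = random_graph(rng, n)
        H = rng.normal(size=(n, 3))
        p = gat_params(rng, 3, 2)
        perm = rng.permutation(n)
        out = gat_layer(Tensor(H), A, p).data
        out_p = gat_layer(Tensor(H[perm]), A[np.ix_(perm, perm)], p).data
        assert np.allclose(out[perm], out_p, atol=1e-10)

    def test_zero_weights_give_zero_output(self):
        p = GatLayerParams(Ws=[Tensor(np.zeros((3, 2)))],
                           a_src=[Tensor(np.zeros((2, 1)))],
                           a_dst=[Tensor(np.zeros((2, 1)))], activation="identity")
        out = gat_layer(Tensor(np.ones((4, 3))), random_graph(np.random.default_rng(0), 4), p)
        assert np.all(out.data == 0)


# --------------------------------------------------------------------------
# Attentive FP
# --------------------------------------------------------------------------


class FakeGraph:
    def __init__(self, node_features, adjacency):
        self.node_features = np.asarray(node_features, float)
        self.adjacency = np.asarray(adjacency, float)


class TestAttFp:
    def test_single_node_readout_is_final_gru_state(self):
        rng = np.random.default_rng(0)
        p = AttFpParams.init(rng, 3, 4, steps=2)
        g = FakeGraph([[1.0, -0.5, 2.0]], [[0.0]])
        out = attfp_encode(g, p).data
        # oracle: unroll manually; single node -> alpha = 1, message = W_msg h
        h = g.node_features @ p.W_in.data
        for k in range(2):
            m = h @ p.W_msg[k].data
            gr = {key: t.data for key, t in p.gru[k].items()}
            z = sigmoid(m @ gr["Wz"] + h @ gr["Uz"] + gr["bz"])
            r = sigmoid(m @ gr["Wr"] + h @ gr["Ur"] + gr["br"])
            h_t = np.tanh(m @ gr["Wh"] + (r * h) @ gr["Uh"] + gr["bh"])
            h = (1 - z) * h + z * h_t
        assert np.allclose(out, h, atol=1e-10)

    def test_two_node_hand_unrolled_oracle(self):
        """Step-by-step unroll of attention + GRU on a 2-node edge."""
        rng = np.random.default_rng(3)
        p = AttFpParams.init(rng, 2, 2, steps=1)
        g = FakeGraph([[1.0, 0.0], [0.0, 1.0]], [[0, 1], [1, 0]])
        out = attfp_encode(g, p).data
        h = g.node_features @ p.W_in.data
        a_s, a_d, W_m = p.align_src[0].data, p.align_dst[0].data, p.W_msg[0].data
        m = np.zeros_like(h)
        for u in range(2):
            nbrs = [0, 1]  # edge + self-loop
            e = np.array([(h[u] @ a_s + h[w] @ a_d).item() for w in nbrs])
            e = np.where(e > 0, e, 0.2 * e)
            al = np.exp(e - e.max())
            al /= al.sum()
            m[u] = sum(a * (h[w] @ W_m) for a, w in zip(al, nbrs))
        gr = {key: t.data for key, t in p.gru[0].items()}
        z = sigmoid(m @ gr["Wz"] + h @ gr["Uz"] + gr["bz"])
        r = sigmoid(m @ gr["Wr"] + h @ gr["Ur"] + gr["br"])
        h_t = np.tanh(m @ gr["Wh"] + (r * h) @ gr["Uh"] + gr["bh"])
        h = (1 - z) * h + z * h_t
        assert np.allclose(out, h.sum(axis=0, keepdims=True), atol=1e-10)

    def test_node_permutation_invariant_readout(self):
        rng = np.random.default_rng(5)
        p = AttFpParams.init(rng, 3, 4, steps=2)
        n = 5
        A = random_graph(rng, n)
        H = rng.normal(size=(n, 3))
        perm = rng.permutation(n)
        out = attfp_encode(FakeGraph(H, A), p).data
        out_p = attfp_encode(FakeGraph(H[perm], A[np.ix_(perm, perm)]), p).data
        assert np.allclose(out, out_p, atol=1e-10)

    def test_requires_at_least_one_step(self):
        with pytest.raises(ValueError):
            AttFpParams.init(np.random.default_rng(0), 3, 4, steps=0)


# --------------------------------------------------------------------------
# Pooling
# --------------------------------------------------------------------------


class TestGlobalPool:
    @pytest.mark.parametrize("mode", ["mean", "sum", "max"])
    def test_single_node_is_identity(self, mode):
        H = Tensor(np.array([[1.0, -2.0, 3.0]]))
        assert np.allclose(global_pool(H, mode).data, H.data)

    def test_arithmetic_identities(self):
        H = Tensor(np.array([[1.0, 3.0], [3.0, 1.0]]))
        assert np.allclose(global_pool(H, "mean").data, [[2.0, 2.0]])
        assert np.allclose(global_pool(H, "sum").data, [[4.0, 4.0]])
        assert np.allclose(global_pool(H, "max").data, [[3.0, 3.0]])

    @pytest.mark.parametrize("mode", ["mean", "sum", "max"])
    def test_row_permutation_invariant(self, mode):
        rng = np.random.default_rng(0)
        H = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        assert np.allclose(global_pool(Tensor(H), mode).data,
                           global_pool(Tensor(H[perm]), mode).data)

    def test_max_pool_gradient_goes_to_argmax(self):
        H = Tensor(np.array([[1.0, 5.0], [3.0, 2.0]]), requires_grad=True)
        global_pool(H, "max").sum().backward()
        assert np.array_equal(H.grad, [[0.0, 1.0], [1.0, 0.0]])

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            global_pool(Tensor(np.zeros((0, 3))), "mean")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            global_pool(Tensor(np.ones((2, 2))), "median")
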