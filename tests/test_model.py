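"""Encoder, discriminator, pair scorer and losses against scalar oracles."""

import numpy as np
import pytest

import freqlink as fl
from freqlink import model as M
from freqlink.autodiff import Tensor
from freqlink.model import EncoderParams
from freqlink.ofd import normalized_laplacian


def make_params(in_dim, hidden, seed=0, dropout=0.0):
    return EncoderParams(in_dim, hidden=hidden, dropout_p=dropout,
                         rng=np.random.default_rng(seed))


class TestGCNEncode:
    def test_single_node_self_loop(self, rng):
        g = fl.BipartiteGraph(["p"], ["m"], {(0, 0)})
        sub = fl.enclosing_subgraph(g, (0, 0), 0)
        # edge removed -> two isolated nodes, A_hat = I
        params = make_params(3, 3)
        params.W1.data = np.eye(3)
        params.W2.data = np.eye(3)
        X = rng.normal(size=(2, 3))
        Z, order = M.gcn_encode(sub, X, params)
        np.testing.assert_allclose(Z.data, np.maximum(X, 0.0))

    def test_zero_w2_zero_output(self, toy4, rng):
        sub = fl.local_subgraph(toy4, (0, 0), 1)
        params = make_params(4, 4)
        params.W2.data = np.zeros((4, 4))
        Z, _ = M.gcn_encode(sub, rng.normal(size=(4, 4)), params)
        assert not Z.data.any()

    def test_dense_oracle(self, toy4, rng):
        sub = fl.local_subgraph(toy4, (1, 0), 1)
        params = make_params(5, 4, seed=3)
        X = rng.normal(size=(toy4.n_nodes, 5))
        Z, order = M.gcn_encode(sub, X, params)
        A = sub.adjacency() + np.eye(sub.n_nodes)
        dinv = 1 / np.sqrt(A.sum(1))
        A_hat = dinv[:, None] * A * dinv[None, :]
        expected = A_hat @ np.maximum(A_hat @ X[order] @ params.W1.data, 0) @ params.W2.data
        np.testing.assert_allclose(Z.data, expected, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        """Relabeling the nodes permutes the embedding rows identically."""
        edges = {(0, 0), (0, 1), (1, 1), (2, 0)}
        ids_a = (["pa", "pb", "pc"], ["ma", "mb"])
        ids_b = (["pc", "pa", "pb"], ["mb", "ma"])   # same topology, new index order
        g1 = fl.BipartiteGraph(*ids_a, edges)
        g2 = fl.BipartiteGraph(*ids_b, {
            (ids_b[0].index(ids_a[0][p]), ids_b[1].index(ids_a[1][m]))
            for p, m in edges})
        feats = {nid: rng.normal(size=4) for nid in ids_a[0] + ids_a[1]}
        X1 = np.array([feats[i] for i in g1.pseudogene_ids + g1.mirna_ids])
        X2 = np.array([feats[i] for i in g2.pseudogene_ids + g2.mirna_ids])
        params = make_params(4, 3, seed=5)
        pair1 = (g1.pseudogene_ids.index("pa"), g1.mirna_ids.index("ma"))
        pair2 = (g2.pseudogene_ids.index("pa"), g2.mirna_ids.index("ma"))
        Z1, o1 = M.gcn_encode(fl.local_subgraph(g1, pair1, 2), X1, params)
        Z2, o2 = M.gcn_encode(fl.local_subgraph(g2, pair2, 2), X2, params)
        names1 = [(g1.pseudogene_ids + g1.mirna_ids)[g] for g in o1]
        names2 = [(g2.pseudogene_ids + g2.mirna_ids)[g] for g in o2]
        assert sorted(names1) == sorted(names2)
        for n in names1:
            np.testing.assert_allclose(Z1.data[names1.index(n)],
                                       Z2.data[names2.index(n)], atol=1e-10)

    def test_dimension_mismatch(self, toy4, rng):
        sub = fl.local_subgraph(toy4, (0, 0), 1)
        with pytest.raises(ValueError):
            M.gcn_encode(sub, rng.normal(size=(2, 4)), make_params(4, 4))


class TestDiscriminator:
    def test_zero_matrix_gives_half(self, rng):
        h = rng.normal(size=4)
        assert float(M.discriminator(h, h, np.zeros((4, 4))).data) == 0.5

    def test_identity_unit_vectors(self):
        e1 = np.eye(4)[0]
        val = float(M.discriminator(e1, e1, np.eye(4)).data)
        assert val == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)

    def test_matches_direct_formula(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        W = rng.normal(size=(5, 5))
        expected = 1 / (1 + np.exp(-(a @ W @ b)))
        assert float(M.discriminator(a, b, W).data) == pytest.approx(expected)

    def test_batched_rows(self, rng):
        A, B = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        W = rng.normal(size=(4, 4))
        out = M.discriminator(A, B, W).data
        for i in range(3):
            assert out[i] == pytest.approx(
                float(M.discriminator(A[i], B[i], W).data))


class TestLossCL:
    def test_uninformative_discriminator_ln2(self, rng):
        H1, H2 = rng.normal(size=(6, 4)), rng.normal(size=(6, 4))
        loss = M.loss_cl(H1, H2, np.zeros((4, 4)), seed=0)
        assert float(loss.data) == pytest.approx(np.log(2))

    def test_perfect_discriminator_vanishes(self):
        # orthonormal rows, W = s(2I - J): aligned pairs -> +s, shuffled -> -s
        n = 5
        H = np.eye(n)
        W = 40.0 * (2 * np.eye(n) - np.ones((n, n)))
        loss = M.loss_cl(H, H, W, seed=1)
        assert float(loss.data) < 1e-6

    def test_loop_oracle(self, rng):
        H1, H2 = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        W = rng.normal(size=(3, 3))
        seed = 11
        shift = int(np.random.default_rng(seed).integers(1, 5))
        perm = np.roll(np.arange(5), shift)
        pos = [1 / (1 + np.exp(-(H1[i] @ W @ H2[i]))) for i in range(5)]
        neg = [1 / (1 + np.exp(-(H1[i] @ W @ H2[perm[i]]))) for i in range(5)]
        expected = -0.5 * (np.mean(np.log(pos)) + np.mean(np.log1p(-np.array(neg))))
        assert float(M.loss_cl(H1, H2, W, seed=seed).data) == pytest.approx(expected)

    def test_single_node_errors(self):
        with pytest.raises(ValueError):
            M.loss_cl(np.ones((1, 2)), np.ones((1, 2)), np.eye(2))

    def test_decreases_under_optimization(self, rng):
        """Training the discriminator alone must reduce the contrastive loss."""
        H1, H2 = rng.normal(size=(8, 4)), rng.normal(size=(8, 4))
        W = Tensor(np.zeros((4, 4)), requires_grad=True)
        losses = []
        for _ in range(50):
            loss = M.loss_cl(H1, H2, W, seed=2)
            loss.backward()
            W.data -= 0.5 * W.grad
            W.grad = None
            losses.append(float(loss.data))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))
        assert losses[-1] < losses[0]


class TestLossKL:
    def test_identical_embeddings_zero(self, rng):
        Z = rng.normal(size=(4, 5))
        assert float(M.loss_kl(Z, Z).data) == 0.0

    def test_closed_form_two_categories(self):
        eps = 0.01
        q = np.log(np.array([[1 - eps, eps]]))
        r = np.log(np.array([[eps, 1 - eps]]))
        expected = (1 - 2 * eps) * np.log((1 - eps) / eps)  # = 4.50322 per row
        assert float(M.loss_kl(q, r).data) == pytest.approx(expected, abs=1e-6)

    def test_nonnegative(self, rng):
        for _ in range(100):
            a, b = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
            assert float(M.loss_kl(a, b).data) >= 0.0

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            M.loss_kl(np.ones((2, 2)), np.ones((3, 2)))
        with pytest.raises(ValueError):
            M.loss_kl(np.ones((0, 2)), np.ones((0, 2)))


class TestLossBCE:
    def test_matching_labels_near_zero(self):
        assert float(M.loss_bce([1, 0], [1.0, 0.0]).data) < 1e-5

    def test_uniform_half_ln2(self):
        assert float(M.loss_bce([1, 0, 1], [0.5] * 3).data) == pytest.approx(np.log(2))

    def test_hand_arithmetic(self):
        expected = -0.5 * (np.log(0.9) + np.log(0.8))
        assert float(M.loss_bce([1, 0], [0.9, 0.2]).data) == pytest.approx(expected)

    def test_empty_batch(self):
        with pytest.raises(ValueError):
            M.loss_bce([], [])


class TestTotalLoss:
    def test_weights_sum_one_leaves_bce(self):
        total = M.total_loss(2.0, 3.0, 0.7, 0.5, 0.5)
        assert float(total.data) == pytest.approx(0.7)

    def test_zero_weights_full_sum(self):
        assert float(M.total_loss(1.0, 2.0, 3.0, 0.0, 0.0).data) == pytest.approx(6.0)

    def test_quarter_weights(self):
        # (1 - 0.25 - 0.25) * (1 + 1) + 1
        assert float(M.total_loss(1.0, 1.0, 1.0, 0.25, 0.25).data) == pytest.approx(2.0)

    def test_softmax_parameterization_keeps_weight_valid(self, rng):
        for _ in range(20):
            logits = rng.normal(scale=3, size=3)
            a, b = M.loss_weights(logits)
            w = 1 - float(a.data) - float(b.data)
            assert -1e-9 <= w <= 1 + 1e-9


class TestScorePairs:
    def test_zero_weights_give_half(self, toy4, rng):
        params = make_params(4, 4)
        for t in (params.mlp_W, params.mlp_b, params.mlp_v, params.mlp_c):
            t.data = np.zeros_like(t.data)
        sub = fl.local_subgraph(toy4, (0, 0), 1)
        Z, order = M.gcn_encode(sub, rng.normal(size=(4, 4)), params)
        s = M.score_pairs(Z, order, [toy4.pair_to_global((0, 0))], params)
        assert float(s.data[0]) == 0.5

    def test_scores_in_unit_interval(self, toy4, rng):
        params = make_params(4, 4, seed=9)
        sub = fl.local_subgraph(toy4, (1, 1), 2)
        Z, order = M.gcn_encode(sub, rng.normal(size=(4, 4)) * 10, params)
        s = M.score_pairs(Z, order, [toy4.pair_to_global((1, 1))], params).data
        assert np.all((s > 0) & (s < 1))

    def test_hand_forward_pass(self):
        params = make_params(2, 2)
        params.mlp_W.data = np.array([[0.1, 0.2], [0.3, -0.1],
                                      [0.0, 0.5], [-0.2, 0.4]])
        params.mlp_b.data = np.array([0.05, -0.05])
        params.mlp_v.data = np.array([[1.0], [-1.0]])
        params.mlp_c.data = np.array([0.1])
        Z = Tensor(np.array([[1.0, 2.0], [0.5, -1.0]]))
        order = np.array([0, 1])
        s = M.score_pairs(Z, order, [(0, 1), (1, 0)], params).data
        for i, (a, b) in enumerate([(0, 1), (1, 0)]):
            z = np.concatenate([Z.data[a], Z.data[b]])
            h = np.maximum(z @ params.mlp_W.data + params.mlp_b.data, 0)
            expected = 1 / (1 + np.exp(-(h @ params.mlp_v.data + 0.1)))
            assert s[i] == pytest.approx(expected.item())

    def test_missing_endpoint(self, toy4, rng):
        params = make_params(4, 4)
        sub = fl.enclosing_subgraph(toy4, (0, 0), 0)   # only p1, m1
        Z, order = M.gcn_encode(sub, rng.normal(size=(4, 4)), params)
        with pytest.raises(KeyError):
            M.score_pairs(Z, order, [toy4.pair_to_global((1, 1))], params)
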