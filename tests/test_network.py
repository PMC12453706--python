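"""Forward-model components against hand-computed oracles."""

import numpy as np
import pytest

from hgmda import (
    ModelDims,
    channel_attention,
    forward,
    hgcn_layer,
    init_model,
    project,
    score_pairs,
    transformer_encode,
)
from hgmda._autodiff import Tensor
from hgmda.experiment import _prepare_inputs
from hgmda import ExperimentConfig, generate_synthetic_dataset


class TestHgcnLayer:
    def test_identity_pass(self, rng):
        X = rng.normal(size=(4, 3))
        out = hgcn_layer(np.eye(4), X, np.eye(3))
        np.testing.assert_allclose(np.asarray(out), np.maximum(X, 0))

    def test_zero_input(self):
        out = hgcn_layer(np.eye(2), np.zeros((2, 3)), np.ones((3, 2)))
        np.testing.assert_array_equal(np.asarray(out), 0.0)

    def test_averaging_cancellation(self):
        L = np.array([[0.5, 0.5], [0.5, 0.5]])
        out = hgcn_layer(L, np.array([[1.0], [-1.0]]), np.array([[1.0]]))
        np.testing.assert_allclose(np.asarray(out), 0.0)

    def test_shape_error(self):
        with pytest.raises(ValueError):
            hgcn_layer(np.eye(3), np.zeros((2, 2)), np.eye(2))


class TestChannelAttention:
    @staticmethod
    def mlp(w1, b1, w2, b2):
        return tuple(Tensor(np.asarray(p, dtype=float)) for p in (w1, b1, w2, b2))

    def test_zero_final_layer_gives_half_gates(self, rng):
        X1, X2 = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        mlp = self.mlp(np.ones((2, 2)), np.zeros(2), np.zeros((2, 2)), np.zeros(2))
        G1, G2, s = channel_attention(X1, X2, mlp)
        np.testing.assert_allclose(np.asarray(s), [0.5, 0.5])
        np.testing.assert_allclose(np.asarray(G1), 0.5 * X1)
        np.testing.assert_allclose(np.asarray(G2), 0.5 * X2)

    def test_identical_views_symmetric_mlp_equal_gates(self, rng):
        X = rng.normal(size=(4, 5))
        # symmetric in the two channels: W1 columns equal, W2 rows equal
        mlp = self.mlp([[1.0, 1.0], [0.5, 0.5]], [0.1, 0.2],
                       [[0.3, -0.2], [0.3, -0.2]], [0.05, 0.05])
        _, _, s = channel_attention(X, X, mlp)
        s = np.asarray(s)
        assert s[0] == pytest.approx(s[1], abs=1e-12)

    def test_hand_stepped_squeeze_and_gate(self):
        X1 = np.array([[1.0, 2.0], [3.0, 4.0]])  # global mean 2.5
        X2 = np.zeros((2, 2))
        W1, b1 = np.array([[1.0, 0.0]]), np.array([0.0])  # picks z1
        W2, b2 = np.array([[2.0], [0.0]]), np.array([0.0, 0.0])
        G1, _, s = channel_attention(X1, X2, self.mlp(W1, b1, W2, b2))
        s_expected = 1.0 / (1.0 + np.exp(-np.array([2 * 2.5, 0.0])))
        np.testing.assert_allclose(np.asarray(s), s_expected, atol=1e-12)
        np.testing.assert_allclose(np.asarray(G1), s_expected[0] * X1, atol=1e-12)

    def test_gates_strictly_inside_unit_interval(self, rng):
        for _ in range(10):
            mlp = self.mlp(rng.normal(size=(3, 2)), rng.normal(size=3),
                           rng.normal(size=(2, 3)), rng.normal(size=2))
            _, _, s = channel_attention(rng.normal(size=(4, 4)),
                                        rng.normal(size=(4, 4)), mlp)
            s = np.asarray(s)
            assert np.all(s > 0) and np.all(s < 1)

    def test_shape_mismatch(self, rng):
        mlp = self.mlp(np.ones((2, 2)), np.zeros(2), np.ones((2, 2)), np.zeros(2))
        with pytest.raises(ValueError):
            channel_attention(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)), mlp)


def _transformer_layer(rng, dm):
    def g(*shape):
        return Tensor(rng.normal(scale=0.3, size=shape), requires_grad=True)

    return {
        "ln1_g": Tensor(np.ones(dm)), "ln1_b": Tensor(np.zeros(dm)),
        "Wq": g(dm, dm), "bq": Tensor(np.zeros(dm)),
        "Wk": g(dm, dm), "bk": Tensor(np.zeros(dm)),
        "Wv": g(dm, dm), "bv": Tensor(np.zeros(dm)),
        "Wo": g(dm, dm), "bo": Tensor(np.zeros(dm)),
        "ln2_g": Tensor(np.ones(dm)), "ln2_b": Tensor(np.zeros(dm)),
        "Wf1": g(dm, 4 * dm), "bf1": Tensor(np.zeros(4 * dm)),
        "Wf2": g(4 * dm, dm), "bf2": Tensor(np.zeros(dm)),
    }


class TestTransformerEncode:
    def test_output_shape_matches_input(self, rng):
        X = rng.normal(size=(7, 8))
        out = transformer_encode(X, [_transformer_layer(rng, 8)], n_head=2)
        assert np.asarray(out).shape == (7, 8)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(6, 8))
        layers = [_transformer_layer(rng, 8) for _ in range(2)]
        out = np.asarray(transformer_encode(X, layers, n_head=4))
        perm = rng.permutation(6)
        out_perm = np.asarray(transformer_encode(X[perm], layers, n_head=4))
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)

    def test_single_head_matches_straight_line_oracle(self, rng):
        """Hand-stepped pre-norm attention + feed-forward on a 2x2 input."""
        X = np.array([[1.0, -0.5], [0.25, 2.0]])
        layer = _transformer_layer(rng, 2)
        out = np.asarray(transformer_encode(X, [layer], n_head=1))

        def ln(M, g, b, eps=1e-5):
            mu = M.mean(axis=1, keepdims=True)
            var = ((M - mu) ** 2).mean(axis=1, keepdims=True)
            return (M - mu) / np.sqrt(var + eps) * g + b

        W = {k: np.asarray(v) for k, v in layer.items()}
        Xn = ln(X, W["ln1_g"], W["ln1_b"])
        Q, K, V = Xn @ W["Wq"], Xn @ W["Wk"], Xn @ W["Wv"]
        scores = Q @ K.T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        attn = (e / e.sum(axis=1, keepdims=True)) @ V
        h = X + attn @ W["Wo"]
        Hn = ln(h, W["ln2_g"], W["ln2_b"])
        expected = h + np.maximum(Hn @ W["Wf1"], 0) @ W["Wf2"]
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_head_divisibility_error(self, rng):
        with pytest.raises(ValueError):
            transformer_encode(rng.normal(size=(3, 6)),
                               [_transformer_layer(rng, 6)], n_head=4)


class TestProjectAndScore:
    def test_identity_projection(self, rng):
        X = rng.normal(size=(3, 4))
        out = project(X, (np.eye(4), np.zeros(4)))
        np.testing.assert_allclose(np.asarray(out), X)

    def test_bias_only(self, rng):
        out = project(rng.normal(size=(3, 4)), (np.zeros((4, 2)), np.array([1.0, -1.0])))
        np.testing.assert_allclose(np.asarray(out), np.tile([1.0, -1.0], (3, 1)))

    def test_random_affine_against_matmul(self, rng):
        X, W, b = rng.normal(size=(3, 4)), rng.normal(size=(4, 2)), rng.normal(size=2)
        np.testing.assert_allclose(np.asarray(project(X, (W, b))), X @ W + b)

    def test_orthogonal_embeddings_score_half(self):
        Z1 = np.array([[1.0, 0.0]])
        Z2 = np.array([[0.0, 1.0]])
        assert np.asarray(score_pairs(Z1, Z2))[0, 0] == pytest.approx(0.5)

    def test_aligned_embeddings_saturate(self):
        v = np.array([[10.0, 0.0]])
        assert np.asarray(score_pairs(v, v))[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_elementwise_sigmoid_oracle(self, rng):
        Zm, Zd = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        S = np.asarray(score_pairs(Zm, Zd))
        for i in range(2):
            for j in range(2):
                assert S[i, j] == pytest.approx(1 / (1 + np.exp(-Zm[i] @ Zd[j])))

    def test_width_mismatch(self, rng):
        with pytest.raises(ValueError):
            score_pairs(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)))


@pytest.fixture(scope="module")
def inputs():
    syn = generate_synthetic_dataset(20, 10, 2, 0.7, 0.05, seed=3)
    cfg = ExperimentConfig(k_neigs=4, clusters=2)
    feats, views = _prepare_inputs(syn.dataset.A.astype(float), cfg, seed=5)
    dims = ModelDims(feats["microbe"].shape[1], feats["disease"].shape[1],
                     d_hidden=16, d_view=8, d_embed=12)
    params = init_model(dims, n_head=2, nlayer=1, seed=9)
    return feats, views, params


class TestForward:

    def test_eval_mode_deterministic(self, inputs):
        feats, views, params = inputs
        s1, _ = forward(feats, views, params, mode="eval")
        s2, _ = forward(feats, views, params, mode="eval")
        np.testing.assert_array_equal(np.asarray(s1), np.asarray(s2))

    def test_zero_parameters_give_half_scores(self, inputs):
        feats, views, params = inputs
        import copy

        zeroed = copy.deepcopy(params)
        for t in zeroed.all_tensors():
            t.data[...] = 0.0
        s, _ = forward(feats, views, zeroed, mode="eval")
        np.testing.assert_allclose(np.asarray(s), 0.5, atol=1e-12)

    def test_score_shape_and_view_embeddings(self, inputs):
        feats, views, params = inputs
        s, view_pairs = forward(feats, views, params, mode="eval")
        assert np.asarray(s).shape == (20, 10)
        Z1, Z2 = view_pairs["microbe"]
        assert np.asarray(Z1).shape == np.asarray(Z2).shape == (20, 8)

    def test_invalid_mode(self, inputs):
        feats, views, params = inputs
        with pytest.raises(ValueError):
            forward(feats, views, params, mode="predict")

    def test_trained_model_separates_planted_blocks(self, planted, tiny_trained):
        from hgmda import score_matrix

        model, _ = tiny_trained
        S = score_matrix(model)
        same = planted.microbe_blocks[:, None] == planted.disease_blocks[None, :]
        assert S[same].mean() > S[~same].mean()
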