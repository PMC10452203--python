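"""Network components: attention, embedders, encoder blocks, head, counting."""

import numpy as np
import pytest

from vocaltab.model import (
    EncoderBlock,
    MLPConfig,
    MLPNet,
    ModelConfig,
    PerFeatureEmbedder,
    VocalTabTransformer,
    attention,
    count_parameters,
)
from vocaltab.nn import bce_with_logits, softmax_last


def brute_force_attention(Q, K, V):
    """Double-loop softmax attention, kept independent of the vectorized path."""
    n, k = Q.shape
    scores = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            scores[i, j] = float(np.dot(Q[i], K[j])) / np.sqrt(k)
    A = np.empty_like(scores)
    for i in range(n):
        e = [np.exp(s - max(scores[i])) for s in scores[i]]
        A[i] = np.array(e) / sum(e)
    return A @ V


def test_attention_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(1, 6))
        k = int(rng.integers(1, 5))
        v = int(rng.integers(1, 5))
        Q, K, V = rng.standard_normal((n, k)), rng.standard_normal((n, k)), rng.standard_normal((n, v))
        np.testing.assert_allclose(attention(Q, K, V), brute_force_attention(Q, K, V), atol=1e-6)


def test_attention_single_row_returns_value_exactly():
    Q, K, V = np.array([[1.0, 2.0]]), np.array([[3.0, 4.0]]), np.array([[5.0, 6.0, 7.0]])
    np.testing.assert_array_equal(attention(Q, K, V), V)


def test_uniform_attention_averages_values():
    Q = np.tile([1.0, -1.0], (4, 1))
    K = np.tile([0.5, 2.0], (4, 1))
    V = np.arange(12, dtype=float).reshape(4, 3)
    out = attention(Q, K, V)
    np.testing.assert_allclose(out, np.tile(V.mean(axis=0), (4, 1)))


def test_attention_rows_sum_to_one():
    rng = np.random.default_rng(1)
    Q, K = rng.standard_normal((7, 3)), rng.standard_normal((7, 3))
    A = softmax_last(Q @ K.T / np.sqrt(3))
    np.testing.assert_allclose(A.sum(axis=1), np.ones(7), atol=1e-6)
    assert (A > 0).all() and (A < 1).all()


def test_attention_zero_key_dim_errors():
    with pytest.raises(ValueError):
        attention(np.empty((2, 0)), np.empty((2, 0)), np.ones((2, 2)))


# -- per-feature embedders --------------------------------------------------


def test_embedder_shape_and_zero_case():
    rng = np.random.default_rng(0)
    emb = PerFeatureEmbedder(n=5, d=8, p=0.0, rng=rng)
    out = emb.forward(rng.standard_normal((3, 5)), training=False, rng=None)
    assert out.shape == (3, 5, 8)
    for p in emb.parameters():
        p.data[...] = 0.0
    out = emb.forward(np.ones((2, 5)), training=False, rng=None)
    assert (out == 0).all()


def test_toy_embedder_matches_hand_computation():
    # one feature, d=2 (hidden width 1): x=1 -> z1=2*1-1=1 -> relu -> 1
    # -> z2 = [1*1+0.5, 1*(-3)+0.5] = [1.5, -2.5] -> relu -> [1.5, 0]
    emb = PerFeatureEmbedder(n=1, d=2, p=0.0, rng=np.random.default_rng(0))
    emb.W1.data[...] = [[2.0]]
    emb.b1.data[...] = [[-1.0]]
    emb.W2.data[...] = [[[1.0, -3.0]]]
    emb.b2.data[...] = [[0.5, 0.5]]
    out = emb.forward(np.array([[1.0]]), training=False, rng=None)
    np.testing.assert_allclose(out, [[[1.5, 0.0]]])


def test_each_feature_has_its_own_embedder():
    rng = np.random.default_rng(2)
    emb = PerFeatureEmbedder(n=3, d=4, p=0.0, rng=rng)
    x = np.array([[1.0, 1.0, 1.0]])
    out = emb.forward(x, training=False, rng=None)
    # same scalar input, different per-feature weights -> different rows
    assert not np.allclose(out[0, 0], out[0, 1])
    # changing feature 0's input leaves other rows untouched
    out2 = emb.forward(np.array([[2.0, 1.0, 1.0]]), training=False, rng=None)
    np.testing.assert_array_equal(out[0, 1:], out2[0, 1:])


# -- encoder blocks ---------------------------------------------------------


def layernorm_ref(x, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def test_zero_weight_encoder_reduces_to_norms_of_input():
    rng = np.random.default_rng(0)
    blk = EncoderBlock(d=4, heads=1, rho=2, p=0.0, rng=rng)
    for lin in (blk.mhsa.wq, blk.mhsa.wk, blk.mhsa.wv, blk.mhsa.wo, blk.ff1, blk.ff2):
        lin.W.data[...] = 0.0
        lin.b.data[...] = 0.0
    x = rng.standard_normal((2, 3, 4))
    out = blk.forward(x, training=False, rng=None)
    np.testing.assert_allclose(out, layernorm_ref(layernorm_ref(x)), atol=1e-12)


def test_encoder_stack_preserves_shape_for_depths_1_to_8():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((2, 5, 8))
    for L in range(1, 9):
        cfg = ModelConfig(n_features=5, embed_dim=8, n_encoders=L, n_heads=2,
                          rho=2, head_hidden=8, dropout_p=0.0, seed=0)
        model = VocalTabTransformer(cfg)
        e = x
        for blk in model.blocks:
            e = blk.forward(e, training=False, rng=None)
        assert e.shape == x.shape
        assert model.forward(rng.standard_normal((4, 5))).shape == (4,)


def test_encoder_is_permutation_equivariant_across_features():
    rng = np.random.default_rng(3)
    blk = EncoderBlock(d=6, heads=2, rho=2, p=0.0, rng=rng)
    e = rng.standard_normal((1, 5, 6))
    perm = np.array([3, 0, 4, 1, 2])
    out = blk.forward(e, training=False, rng=None)
    out_perm = blk.forward(e[:, perm], training=False, rng=None)
    np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-10)


def test_single_encoder_block_matches_stepwise_reference():
    # scripted post-norm reference with h=1, d=4, rho=2 on a fixed 3x4 input
    rng = np.random.default_rng(7)
    blk = EncoderBlock(d=4, heads=1, rho=2, p=0.0, rng=rng)
    x = np.random.default_rng(11).standard_normal((1, 3, 4))
    q = x @ blk.mhsa.wq.W.data + blk.mhsa.wq.b.data
    k = x @ blk.mhsa.wk.W.data + blk.mhsa.wk.b.data
    v = x @ blk.mhsa.wv.W.data + blk.mhsa.wv.b.data
    A = softmax_last(q @ np.swapaxes(k, -1, -2) / 2.0)
    att = (A @ v) @ blk.mhsa.wo.W.data + blk.mhsa.wo.b.data
    x1 = layernorm_ref(x + att) * blk.ln1.gamma.data + blk.ln1.beta.data
    ff = np.maximum(x1 @ blk.ff1.W.data + blk.ff1.b.data, 0.0)
    ff = ff @ blk.ff2.W.data + blk.ff2.b.data
    expected = layernorm_ref(x1 + ff) * blk.ln2.gamma.data + blk.ln2.beta.data
    np.testing.assert_allclose(blk.forward(x, training=False, rng=None), expected, atol=1e-10)


# -- head and full forward --------------------------------------------------


def test_default_head_dimensions():
    model = VocalTabTransformer(ModelConfig(n_encoders=0))
    assert model.head.fc1.W.data.shape == (96 * 64, 2048)
    assert model.head.fc2.W.data.shape == (2048, 1)


def test_zero_final_layer_gives_probability_half(tiny_model_config):
    model = VocalTabTransformer(tiny_model_config)
    model.head.fc2.W.data[...] = 0.0
    model.head.fc2.b.data[...] = 0.0
    out = model.forward(np.random.default_rng(0).standard_normal((5, 20)))
    np.testing.assert_array_equal(out, np.full(5, 0.5))


def test_outputs_strictly_inside_unit_interval(tiny_model_config):
    model = VocalTabTransformer(tiny_model_config)
    out = model.forward(np.random.default_rng(1).standard_normal((8, 20)))
    assert ((out > 0) & (out < 1)).all()


def test_eval_forward_is_deterministic(tiny_model_config):
    model = VocalTabTransformer(tiny_model_config)
    X = np.random.default_rng(2).standard_normal((6, 20))
    np.testing.assert_array_equal(model.forward(X), model.forward(X))


def test_wrong_input_width_errors(tiny_model_config):
    model = VocalTabTransformer(tiny_model_config)
    with pytest.raises(ValueError):
        model.forward(np.zeros((2, 7)))


# -- parameter counting -----------------------------------------------------


def test_hand_summed_count_for_minimal_config():
    # n=1, d=2 (h=1), L=0, H=2:
    # embedder 1*[(1+1)+(1*2+2)] = 6; head (1*2*2+2)+(2+1) = 9; total 15
    cfg = ModelConfig(n_features=1, embed_dim=2, n_encoders=0, n_heads=1,
                      rho=1, head_hidden=2)
    assert count_parameters(cfg) == 15
    assert VocalTabTransformer(cfg).num_parameters() == 15


def test_closed_form_matches_introspection_for_random_configs():
    rng = np.random.default_rng(0)
    for _ in range(20):
        heads = int(rng.choice([1, 2, 4]))
        d = heads * 2 * int(rng.integers(1, 4))
        cfg = ModelConfig(
            n_features=int(rng.integers(1, 12)),
            embed_dim=d,
            n_encoders=int(rng.integers(0, 4)),
            n_heads=heads,
            rho=int(rng.integers(1, 4)),
            head_hidden=int(rng.integers(1, 64)),
        )
        assert count_parameters(cfg) == VocalTabTransformer(cfg).num_parameters()


def test_head_contribution_is_linear_in_hidden_width():
    base = ModelConfig(n_features=4, embed_dim=8, n_encoders=2, head_hidden=32, rho=2)
    doubled = ModelConfig(n_features=4, embed_dim=8, n_encoders=2, head_hidden=64, rho=2)
    assert count_parameters(doubled) - count_parameters(base) == 32 * (4 * 8 + 2)


def test_invalid_configs_error():
    with pytest.raises(ValueError):
        ModelConfig(embed_dim=6, n_heads=4)
    with pytest.raises(ValueError):
        ModelConfig(dropout_p=1.0)
    with pytest.raises(ValueError):
        ModelConfig(embed_dim=7)


# -- gradients --------------------------------------------------------------


@pytest.mark.parametrize("kind", ["vocaltab", "mlp"])
def test_backprop_matches_numerical_gradients(kind):
    if kind == "vocaltab":
        model = VocalTabTransformer(
            ModelConfig(n_features=3, embed_dim=4, n_encoders=2, n_heads=2,
                        rho=2, head_hidden=5, dropout_p=0.0, seed=1)
        )
        X = np.random.default_rng(0).standard_normal((4, 3))
    else:
        model = MLPNet(MLPConfig(n_features=3, hidden=(6, 4), dropout_p=0.0, seed=1))
        X = np.random.default_rng(0).standard_normal((5, 3))
    y = (np.arange(X.shape[0]) % 2).astype(float)

    def loss():
        return bce_with_logits(model.forward_logits(X, training=True,
                                                    rng=np.random.default_rng(1)), y)[0]

    base_logits = model.forward_logits(X, training=True, rng=np.random.default_rng(1))
    _, dlog = bce_with_logits(base_logits, y)
    model.zero_grad()
    model.backward(dlog)
    rng = np.random.default_rng(2)
    for p in model.parameters():
        idx = tuple(rng.integers(0, s) for s in p.data.shape)
        eps = 1e-6
        old = p.data[idx]
        p.data[idx] = old + eps
        lp = loss()
        p.data[idx] = old - eps
        lm = loss()
        p.data[idx] = old
        num = (lp - lm) / (2 * eps)
        denom = max(1e-8, abs(num) + abs(p.grad[idx]))
        assert abs(num - p.grad[idx]) / denom < 1e-4
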