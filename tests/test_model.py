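import numpy as np
import pytest
from scipy.special import erf, softmax as scipy_softmax

from smtrace.model import (
    Encoder,
    HeadSpec,
    ModelConfig,
    assemble_input,
    count_parameters,
    embed_traces,
    head_predict,
    init_weights,
    load_weights,
    save_weights,
    tokenize,
    unstack_frames,
    weights_fingerprint,
)


class TestTokenize:
    def test_token_count(self):
        W = np.zeros((100, 16))
        tokens = tokenize(np.zeros((2000, 2)), W, np.zeros(16), 50)
        assert tokens.shape == (40, 16)

    def test_zero_weights_gives_bias(self):
        b = np.arange(8.0)
        tokens = tokenize(np.ones((10, 2)), np.zeros((10, 8)), b, 5)
        assert np.allclose(tokens, b)

    def test_matrix_product_oracle(self, rng):
        # hand-computed oracle: token i = flatten(patch i) @ W + b
        trace = rng.normal(size=(15, 2))
        W = rng.normal(size=(10, 4))
        b = rng.normal(size=4)
        tokens = tokenize(trace, W, b, 5)
        for i in range(3):
            expected = trace[5 * i : 5 * (i + 1)].reshape(-1) @ W + b
            assert np.allclose(tokens[i], expected)

    def test_indivisible_length_errors(self):
        with pytest.raises(ValueError):
            tokenize(np.zeros((47, 2)), np.zeros((100, 8)), np.zeros(8), 50)


class TestAssembleInput:
    def test_length_plus_one(self, rng):
        tokens = rng.normal(size=(40, 8))
        out = assemble_input(tokens, np.zeros((41, 8)), np.zeros(8))
        assert out.shape == (41, 8)

    def test_zero_position_embedding(self, rng):
        tokens = rng.normal(size=(3, 4))
        cls = rng.normal(size=4)
        out = assemble_input(tokens, np.zeros((10, 4)), cls)
        assert np.allclose(out[0], cls)
        assert np.allclose(out[1:], tokens)

    def test_single_patch(self, rng):
        out = assemble_input(rng.normal(size=(1, 4)), np.zeros((2, 4)),
                             np.zeros(4))
        assert out.shape == (2, 4)

    def test_short_position_embedding_errors(self, rng):
        with pytest.raises(ValueError):
            assemble_input(rng.normal(size=(5, 4)), np.zeros((5, 4)),
                           np.zeros(4))


class TestEncoder:
    def test_zero_layers_identity_path(self, rng):
        # N=0 reduces the encoder to tokenizer + unstack
        cfg = ModelConfig(patch_width=5, embed_dim=8, n_layers=0, n_heads=2,
                          n_positions=4)
        enc = Encoder(cfg, seed=1)
        x = rng.normal(size=(1, 15, 2))
        z0, frames = enc.forward(x)
        w = enc.weights
        tokens = tokenize(x[0], w["tokenizer/W"], w["tokenizer/b"], 5)
        seq = assemble_input(tokens, w["position_embedding"], w["class_token"])
        assert np.allclose(z0[0], seq[0])
        expected = (seq[1:] @ w["unstack/W"]).reshape(15, 8)
        assert np.allclose(frames[0], expected)

    def test_determinism(self, rng):
        cfg = ModelConfig(patch_width=5, embed_dim=8, n_layers=2, n_heads=2,
                          n_positions=4)
        enc = Encoder(cfg, seed=2)
        x = rng.normal(size=(2, 15, 2))
        z0a, fa = enc.forward(x)
        z0b, fb = enc.forward(x)
        assert np.array_equal(z0a, z0b) and np.array_equal(fa, fb)

    def test_single_layer_hand_oracle(self, rng):
        # independent re-implementation of one pre-norm attention layer
        cfg = ModelConfig(patch_width=1, embed_dim=4, n_layers=1, n_heads=1,
                          n_positions=3, n_channels=2)
        enc = Encoder(cfg, seed=3)
        x = rng.normal(size=(1, 2, 2))
        z0, frames = enc.forward(x)
        w = enc.weights

        def ln(v, g, b, eps=1e-5):
            mu = v.mean(-1, keepdims=True)
            var = v.var(-1, keepdims=True)
            return (v - mu) / np.sqrt(var + eps) * g + b

        tokens = x[0] @ w["tokenizer/W"] + w["tokenizer/b"]
        seq = np.vstack([w["class_token"], tokens]) + w["position_embedding"][:3]
        h = ln(seq, w["layer_0/ln1/g"], w["layer_0/ln1/b"])
        qkv = h @ w["layer_0/attn/Wqkv"] + w["layer_0/attn/bqkv"]
        q, k, v = qkv[:, :4], qkv[:, 4:8], qkv[:, 8:]
        att = scipy_softmax(q @ k.T / 2.0, axis=-1)  # sqrt(d_head)=2
        ctx = att @ v
        x1 = seq + ctx @ w["layer_0/attn/Wo"] + w["layer_0/attn/bo"]
        h2 = ln(x1, w["layer_0/ln2/g"], w["layer_0/ln2/b"])
        pre = h2 @ w["layer_0/ffn/W1"] + w["layer_0/ffn/b1"]
        act = 0.5 * pre * (1 + erf(pre / np.sqrt(2)))
        out = x1 + act @ w["layer_0/ffn/W2"] + w["layer_0/ffn/b2"]
        assert np.allclose(z0[0], out[0], atol=1e-6)
        expected_frames = (out[1:] @ w["unstack/W"]).reshape(2, 4)
        assert np.allclose(frames[0], expected_frames, atol=1e-6)

    def test_nan_weights_surface(self, rng):
        cfg = ModelConfig(patch_width=5, embed_dim=8, n_layers=1, n_heads=2,
                          n_positions=4)
        enc = Encoder(cfg, seed=4)
        enc.weights["tokenizer/W"][0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            enc.forward(rng.normal(size=(1, 15, 2)))

    def test_gradients_match_finite_differences(self, rng):
        cfg = ModelConfig(patch_width=5, embed_dim=8, n_layers=2, n_heads=2,
                          n_positions=5)
        enc = Encoder(cfg, seed=5)
        x = rng.normal(size=(2, 15, 2))
        a = rng.normal(size=(2, 8))
        b = rng.normal(size=(2, 15, 8))
        z0, fr, cache = enc.forward(x, want_cache=True)
        grads = enc.backward(cache, a, b)
        eps = 1e-6
        for name, W in enc.weights.items():
            idx = tuple(rng.integers(0, s) for s in W.shape)
            orig = W[idx]
            W[idx] = orig + eps
            zp, fp = enc.forward(x)
            W[idx] = orig - eps
            zm, fm = enc.forward(x)
            W[idx] = orig
            fd = ((a * (zp - zm)).sum() + (b * (fp - fm)).sum()) / (2 * eps)
            an = grads[name][idx]
            assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd)), name


class TestUnstack:
    def test_zero_input(self):
        out = unstack_frames(np.zeros(4), np.zeros((4, 20)), 5, 4)
        assert out.shape == (5, 4) and np.all(out == 0)

    def test_width_one_is_linear_map(self, rng):
        z = rng.normal(size=6)
        W = rng.normal(size=(6, 6))
        assert np.allclose(unstack_frames(z, W, 1, 6), (z @ W)[None, :])

    def test_reshape_oracle(self, rng):
        z = rng.normal(size=8)
        W = rng.normal(size=(8, 3 * 8))
        out = unstack_frames(z, W, 3, 8)
        expected = np.array([z @ W[:, 8 * i : 8 * (i + 1)] for i in range(3)])
        assert np.allclose(out, expected)


class TestEmbedTraces:
    def test_batch_invariance(self, rng, tiny_model_cfg):
        enc = Encoder(tiny_model_cfg, seed=6)
        traces = [rng.normal(size=(500, 2)) for _ in range(3)]
        single = embed_traces(traces[:1], enc)
        many = embed_traces(traces, enc)
        assert np.allclose(single[0].trace_embedding, many[0].trace_embedding)
        assert np.allclose(single[0].frame_embeddings, many[0].frame_embeddings)

    def test_one_color_finite(self, tiny_model_cfg, rng):
        enc = Encoder(tiny_model_cfg, seed=6)
        tr = np.stack([rng.normal(size=500), np.zeros(500)], axis=1)
        emb = embed_traces([tr], enc)[0]
        assert np.all(np.isfinite(emb.trace_embedding))
        assert emb.frame_embeddings.shape == (500, 32)

    def test_channel_swap_differs(self, tiny_model_cfg, rng):
        enc = Encoder(tiny_model_cfg, seed=6)
        tr = rng.normal(size=(500, 2)) + 5.0
        a = embed_traces([tr], enc)[0].trace_embedding
        b = embed_traces([tr[:, ::-1]], enc)[0].trace_embedding
        assert not np.allclose(a, b)

    def test_truncation_warns(self, tiny_model_cfg, rng):
        enc = Encoder(tiny_model_cfg, seed=6)
        with pytest.warns(UserWarning, match="truncating"):
            emb = embed_traces([rng.normal(size=(123, 2))], enc)[0]
        assert emb.frame_embeddings.shape[0] == 100


class TestHeads:
    def test_zero_head_uniform(self):
        head = HeadSpec("t", "trace", 4, np.zeros((8, 4)), np.zeros(4))
        p = head_predict(np.ones(8), head)
        assert np.allclose(p, 0.25)

    def test_large_logit_argmax(self):
        b = np.zeros(4)
        b[2] = 50.0
        head = HeadSpec("t", "trace", 4, np.zeros((8, 4)), b)
        assert np.argmax(head_predict(np.ones(8), head)) == 2

    def test_softmax_oracle(self, rng):
        W = rng.normal(size=(8, 5))
        b = rng.normal(size=5)
        z = rng.normal(size=8)
        head = HeadSpec("t", "trace", 5, W, b)
        assert np.allclose(head_predict(z, head),
                           scipy_softmax(z @ W + b), atol=1e-6)
        assert abs(head_predict(z, head).sum() - 1.0) < 1e-12


class TestCountParameters:
    def test_minimal_config(self):
        cfg = ModelConfig(patch_width=1, embed_dim=1, n_layers=0, n_heads=1,
                          n_positions=2)
        # tokenizer (1*2*1 + 1) + class (1) + position (2) + unstack (1)
        assert count_parameters(cfg) == 3 + 1 + 2 + 1

    def test_introspection_oracle(self):
        cfg = ModelConfig(patch_width=50, embed_dim=96, n_layers=4, n_heads=4)
        total = sum(w.size for w in init_weights(cfg).values())
        assert count_parameters(cfg) == total

    def test_layer_linearity(self):
        base = ModelConfig(embed_dim=32, n_layers=2, n_positions=11)
        double = ModelConfig(embed_dim=32, n_layers=4, n_positions=11)
        per_layer = (count_parameters(double) - count_parameters(base)) / 2
        none = ModelConfig(embed_dim=32, n_layers=0, n_positions=11)
        assert count_parameters(base) == count_parameters(none) + 2 * per_layer


class TestWeightsIO:
    def test_roundtrip(self, tmp_path, tiny_model_cfg):
        w = init_weights(tiny_model_cfg, seed=9)
        save_weights(w, str(tmp_path / "w.h5"))
        w2 = load_weights(str(tmp_path / "w.h5"))
        assert set(w) == set(w2)
        for k in w:
            assert np.array_equal(w[k], w2[k])
        assert weights_fingerprint(w) == weights_fingerprint(w2)

    def test_fingerprint_sensitivity(self, tiny_model_cfg):
        w = init_weights(tiny_model_cfg, seed=9)
        fp = weights_fingerprint(w)
        w["class_token"] = w["class_token"] + 1e-9
        assert weights_fingerprint(w) != fp
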