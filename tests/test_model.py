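"""Encoder correctness against explicit-loop oracles, attention invariants,
pad-mask behaviour, gradients, and weight archives."""

import math

import numpy as np
import pytest

import docrex as dx
from docrex.model import (
    backward_batch,
    forward_batch,
    parameter_count,
    predict_proba_scores,
)
from docrex.pretreat import TokenSequence
from docrex.train import cross_entropy


def make_seq(ids, n_pad=0):
    ids = list(ids) + [0] * n_pad
    n = len(ids)
    mask = np.array([1] * (n - n_pad) + [0] * n_pad)
    return TokenSequence(
        tokens=[f"t{i}" for i in ids],
        ids=np.array(ids),
        positions=np.arange(n),
        segment_ids=np.zeros(n, dtype=int),
        mask=mask,
    )


# -- explicit-loop oracles ---------------------------------------------------


def embed_oracle(seq, params):
    n = len(seq.ids)
    d = params["tok_emb"].shape[1]
    out = np.zeros((n, d))
    for i in range(n):
        for j in range(d):
            out[i, j] = (params["tok_emb"][seq.ids[i], j]
                         + params["seg_emb"][seq.segment_ids[i], j]
                         + params["pos_emb"][i, j])
    return out


def softmax_oracle(row):
    e = [math.exp(x - max(row)) for x in row]
    z = sum(e)
    return [v / z for v in e]


def attention_head_oracle(s, wq, wk, wv):
    n, d = s.shape
    l = wq.shape[1]
    q = np.array([[sum(s[i, a] * wq[a, b] for a in range(d)) for b in range(l)]
                  for i in range(n)])
    k = np.array([[sum(s[i, a] * wk[a, b] for a in range(d)) for b in range(l)]
                  for i in range(n)])
    v = np.array([[sum(s[i, a] * wv[a, b] for a in range(d)) for b in range(l)]
                  for i in range(n)])
    out = np.zeros((n, l))
    for i in range(n):
        logits = [sum(q[i, c] * k[j, c] for c in range(l)) / math.sqrt(l)
                  for j in range(n)]
        a_row = softmax_oracle(logits)
        for c in range(l):
            out[i, c] = sum(a_row[j] * v[j, c] for j in range(n))
    return out


def layer_norm_oracle(x, g, b, eps):
    out = np.zeros_like(x)
    for i in range(x.shape[0]):
        mu = x[i].mean()
        var = ((x[i] - mu) ** 2).mean()
        out[i] = g * (x[i] - mu) / math.sqrt(var + eps) + b
    return out


def multi_head_oracle(s, params, cfg, stack=0):
    p = f"stack{stack}."
    l = cfg.head_dim
    heads = []
    for i in range(cfg.n_heads):
        cols = slice(i * l, (i + 1) * l)
        heads.append(attention_head_oracle(
            s, params[p + "wq"][:, cols], params[p + "wk"][:, cols],
            params[p + "wv"][:, cols]))
    o = np.concatenate(heads, axis=1)
    if cfg.architecture == "standard":
        o = o @ params[p + "wo"]
    return layer_norm_oracle(s + o, params[p + "ln1_g"], params[p + "ln1_b"],
                             cfg.layer_norm_eps)


def ffn_oracle(m, params, cfg, stack=0):
    p = f"stack{stack}."
    hidden = np.maximum(m @ params[p + "w1"] + params[p + "b1"], 0.0)
    out = hidden @ params[p + "w2"] + params[p + "b2"]
    if cfg.architecture == "standard":
        out = layer_norm_oracle(m + out, params[p + "ln2_g"],
                                params[p + "ln2_b"], cfg.layer_norm_eps)
    return out


def forward_oracle(seq, params, cfg):
    s = embed_oracle(seq, params)
    for k in range(cfg.n_stacks):
        s = ffn_oracle(multi_head_oracle(s, params, cfg, k), params, cfg, k)
    return params["w_pred"] @ s[0]


# -- tests -------------------------------------------------------------------


class TestEmbed:
    def test_zero_tables_give_zero_matrix(self, tiny_model):
        cfg, params = tiny_model
        zero = {k: np.zeros_like(v) for k, v in params.items()}
        seq = make_seq([1, 2, 3])
        assert np.all(dx.embed(seq, zero) == 0.0)

    def test_one_hot_token_table(self):
        params = {
            "tok_emb": np.eye(5),
            "seg_emb": np.zeros((2, 5)),
            "pos_emb": np.zeros((6, 5)),
        }
        seq = make_seq([3, 0, 4])
        s0 = dx.embed(seq, params)
        assert np.array_equal(s0, np.eye(5)[[3, 0, 4]])

    def test_matches_loop_oracle(self, tiny_model):
        cfg, params = tiny_model
        seq = make_seq([1, 5, 9, 2])
        np.testing.assert_allclose(dx.embed(seq, params),
                                   embed_oracle(seq, params), atol=1e-12)

    def test_out_of_range_id_raises(self, tiny_model):
        cfg, params = tiny_model
        with pytest.raises(ValueError):
            dx.embed(make_seq([99]), params)


class TestAttentionHead:
    def test_single_position_passes_value_through(self, tiny_model):
        cfg, params = tiny_model
        rng = np.random.default_rng(0)
        s = rng.normal(size=(1, cfg.d_model))
        wq, wk, wv = (rng.normal(size=(cfg.d_model, 3)) for _ in range(3))
        out = dx.attention_head(s, wq, wk, wv)
        np.testing.assert_allclose(out, s @ wv, atol=1e-12)

    def test_zero_query_gives_uniform_attention(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=(4, 6))
        wk, wv = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        out = dx.attention_head(s, np.zeros((6, 2)), wk, wv)
        expected = np.repeat((s @ wv).mean(axis=0, keepdims=True), 4, axis=0)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=(3, 4))
        wq, wk, wv = (rng.normal(size=(4, 2)) for _ in range(3))
        np.testing.assert_allclose(
            dx.attention_head(s, wq, wk, wv),
            attention_head_oracle(s, wq, wk, wv), atol=1e-10)

    def test_nonfinite_input_raises(self):
        s = np.full((2, 4), np.nan)
        w = np.zeros((4, 2))
        with pytest.raises(ValueError):
            dx.attention_head(s, w, w, w)


class TestMultiHeadAndFfn:
    @pytest.mark.parametrize("arch", ["standard", "literal"])
    def test_multi_head_matches_per_head_oracle(self, arch):
        rng = np.random.default_rng(3)
        cfg = dx.ModelConfig(n_stacks=1, n_heads=2, d_model=4, n_max=4,
                             vocab_size=5, dropout=0.0, architecture=arch)
        params = dx.init_params(cfg, rng)
        params = {k: v * 10 if v.ndim > 1 else v for k, v in params.items()}
        s = rng.normal(size=(3, 4))
        np.testing.assert_allclose(
            dx.multi_head(s, params, cfg),
            multi_head_oracle(s, params, cfg), atol=1e-10)

    def test_rows_are_normalized_before_gain_bias(self, tiny_model):
        cfg, params = tiny_model
        rng = np.random.default_rng(4)
        s = rng.normal(size=(5, cfg.d_model))
        m = dx.multi_head(s, params, cfg)
        g = params["stack0.ln1_g"]
        b = params["stack0.ln1_b"]
        xhat = (m - b) / g
        np.testing.assert_allclose(xhat.mean(axis=1), 0.0, atol=1e-8)
        np.testing.assert_allclose(xhat.var(axis=1), 1.0, atol=1e-6)

    def test_ffn_zero_weights_reduce_to_layer_norm(self, tiny_model):
        cfg, params = tiny_model
        p = {k: (np.zeros_like(v) if k.startswith("stack0.w") or
                 k.startswith("stack0.b") else v)
             for k, v in params.items()}
        rng = np.random.default_rng(5)
        m = rng.normal(size=(3, cfg.d_model))
        expected = layer_norm_oracle(m, params["stack0.ln2_g"],
                                     params["stack0.ln2_b"], cfg.layer_norm_eps)
        np.testing.assert_allclose(dx.ffn(m, p, cfg), expected, atol=1e-10)

    def test_ffn_matches_loop_oracle_single_position(self, tiny_model):
        cfg, params = tiny_model
        rng = np.random.default_rng(6)
        m = rng.normal(size=(1, cfg.d_model))
        np.testing.assert_allclose(dx.ffn(m, params, cfg),
                                   ffn_oracle(m, params, cfg), atol=1e-10)

    def test_ffn_is_position_wise(self, tiny_model):
        cfg, params = tiny_model
        rng = np.random.default_rng(7)
        m = rng.normal(size=(4, cfg.d_model))
        perm = np.array([2, 0, 3, 1])
        np.testing.assert_allclose(dx.ffn(m[perm], params, cfg),
                                   dx.ffn(m, params, cfg)[perm], atol=1e-12)


class TestForward:
    @pytest.mark.parametrize("arch", ["standard", "literal"])
    def test_matches_composed_loop_oracle(self, arch):
        rng = np.random.default_rng(8)
        cfg = dx.ModelConfig(n_stacks=2, n_heads=2, d_model=8, n_max=5,
                             vocab_size=9, n_classes=3, dropout=0.0,
                             architecture=arch)
        params = dx.init_params(cfg, rng)
        params = {k: v * 10 if v.ndim > 1 else v for k, v in params.items()}
        seq = make_seq(rng.integers(0, 9, size=5))
        np.testing.assert_allclose(dx.forward(seq, params, cfg),
                                   forward_oracle(seq, params, cfg), atol=1e-8)

    def test_zero_stacks_expose_embedding_row(self):
        cfg = dx.ModelConfig(n_stacks=0, n_heads=1, d_model=4, n_max=3,
                             vocab_size=5, n_classes=4, dropout=0.0)
        params = dx.init_params(cfg, np.random.default_rng(9))
        params["w_pred"] = np.eye(4)
        seq = make_seq([2, 1, 0])
        np.testing.assert_allclose(dx.forward(seq, params, cfg),
                                   dx.embed(seq, params)[0], atol=1e-12)

    def test_probabilities_sum_to_one(self, tiny_model):
        cfg, params = tiny_model
        seq = make_seq([1, 2, 3, 4])
        probs = predict_proba_scores(dx.forward(seq, params, cfg))
        assert probs.shape == (cfg.n_classes,)
        assert probs.sum() == pytest.approx(1.0)

    def test_padding_never_changes_cls_scores(self, tiny_model):
        cfg, params = tiny_model
        base = dx.forward(make_seq([1, 2, 3]), params, cfg)
        for n_pad in (1, 2, 3):
            padded = dx.forward(make_seq([1, 2, 3], n_pad=n_pad), params, cfg)
            np.testing.assert_allclose(padded, base, atol=1e-9)


class TestAttentionExport:
    def test_rows_sum_to_one_every_head(self, tiny_model):
        cfg, params = tiny_model
        seq = make_seq([1, 2, 3, 4, 5])
        for k in range(cfg.n_stacks):
            attn = dx.export_attention(seq, params, cfg, k)
            assert attn.shape == (cfg.n_heads, 5, 5)
            np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_token_attention_is_one(self, tiny_model):
        cfg, params = tiny_model
        attn = dx.export_attention(make_seq([3]), params, cfg, 0)
        np.testing.assert_allclose(attn, 1.0)

    def test_matches_attention_head_internal_matrix(self, tiny_model):
        cfg, params = tiny_model
        seq = make_seq([1, 2, 3])
        attn = dx.export_attention(seq, params, cfg, 0)
        s0 = dx.embed(seq, params)
        l = cfg.head_dim
        for h in range(cfg.n_heads):
            cols = slice(h * l, (h + 1) * l)
            _, a = dx.attention_head(
                s0, params["stack0.wq"][:, cols], params["stack0.wk"][:, cols],
                params["stack0.wv"][:, cols], mask=seq.mask[:3],
                return_attention=True)
            np.testing.assert_allclose(attn[h], a, atol=1e-10)

    def test_out_of_range_stack_raises(self, tiny_model):
        cfg, params = tiny_model
        with pytest.raises(IndexError):
            dx.export_attention(make_seq([1]), params, cfg, cfg.n_stacks)


def test_sqrt_head_dim_scaling_keeps_logit_variance_flat():
    """With i.i.d. unit-variance q/k entries, dividing by sqrt(l) keeps the
    attention-logit variance near 1 regardless of the head dimension."""
    rng = np.random.default_rng(10)
    variances = []
    for l in (2, 8, 32, 128):
        q = rng.normal(size=(2000, l))
        k = rng.normal(size=(2000, l))
        logits = (q * k).sum(axis=1) / np.sqrt(l)
        variances.append(logits.var())
    assert all(abs(v - 1.0) < 0.15 for v in variances)


class TestGradients:
    @pytest.mark.parametrize("arch", ["standard", "literal"])
    def test_backward_matches_numerical_gradient(self, arch):
        rng = np.random.default_rng(11)
        cfg = dx.ModelConfig(n_stacks=2, n_heads=2, d_model=8, n_max=6,
                             vocab_size=11, n_classes=3, dropout=0.0,
                             architecture=arch)
        params = dx.init_params(cfg, rng)
        ids = rng.integers(0, 11, size=(2, 6))
        seg = np.zeros((2, 6), dtype=int)
        mask = np.ones((2, 6), dtype=int)
        mask[1, 4:] = 0
        y = np.array([0, 2])

        def loss_fn(p):
            scores, _ = forward_batch(ids, seg, mask, p, cfg)
            return cross_entropy(scores, y)[0]

        scores, cache = forward_batch(ids, seg, mask, params, cfg)
        _, dscores = cross_entropy(scores, y)
        grads = backward_batch(dscores, cache, params, cfg)
        for name, g in grads.items():
            for fi in rng.integers(0, g.size, size=min(4, g.size)):
                p2 = {k: v.copy() for k, v in params.items()}
                eps = 1e-6
                p2[name].flat[fi] += eps
                up = loss_fn(p2)
                p2[name].flat[fi] -= 2 * eps
                down = loss_fn(p2)
                numeric = (up - down) / (2 * eps)
                assert g.flat[fi] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestWeightArchive:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        cfg, params = tiny_model
        path = tmp_path / "weights.npz"
        dx.save_params(params, path)
        loaded = dx.load_pretrained(path, cfg)
        assert set(loaded) == set(params)
        for k in params:
            np.testing.assert_array_equal(loaded[k], params[k])

    def test_truncated_archive_names_missing_tensors(self, tiny_model, tmp_path):
        cfg, params = tiny_model
        partial = {k: v for k, v in params.items() if k != "stack1.wq"}
        path = tmp_path / "partial.npz"
        dx.save_params(partial, path)
        with pytest.raises(ValueError, match="stack1.wq"):
            dx.load_pretrained(path, cfg)

    def test_shape_mismatch_reported(self, tiny_model, tmp_path):
        cfg, params = tiny_model
        bad = dict(params)
        bad["w_pred"] = np.zeros((7, 3))
        path = tmp_path / "bad.npz"
        dx.save_params(bad, path)
        with pytest.raises(ValueError, match="w_pred"):
            dx.load_pretrained(path, cfg)

    def test_name_mapping_applied(self, tiny_model, tmp_path):
        cfg, params = tiny_model
        renamed = {("embeddings.word" if k == "tok_emb" else k): v
                   for k, v in params.items()}
        path = tmp_path / "renamed.npz"
        dx.save_params(renamed, path)
        loaded = dx.load_pretrained(path, cfg,
                                    name_map={"embeddings.word": "tok_emb"})
        np.testing.assert_array_equal(loaded["tok_emb"], params["tok_emb"])

    def test_loaded_model_is_deterministic(self, tiny_model, tmp_path):
        cfg, params = tiny_model
        path = tmp_path / "w.npz"
        dx.save_params(params, path)
        loaded = dx.load_pretrained(path, cfg)
        seq = make_seq([1, 2, 3, 4])
        a = dx.forward(seq, loaded, cfg)
        b = dx.forward(seq, loaded, cfg)
        np.testing.assert_array_equal(a, b)


def test_parameter_count_and_config_validation():
    cfg = dx.ModelConfig(n_stacks=1, n_heads=2, d_model=4, n_max=3,
                         vocab_size=5, n_classes=2)
    params = dx.init_params(cfg, np.random.default_rng(0))
    assert parameter_count(params) == sum(v.size for v in params.values())
    with pytest.raises(ValueError):
        dx.ModelConfig(n_heads=3, d_model=8)
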