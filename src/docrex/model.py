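"""Transformer encoder and relation classifier, in plain NumPy.

The model is a stack of k transformer encoder blocks over a summed
token/segment/position embedding, followed by a linear classifier on the
final representation of the sequence-initial ``[CLS]`` token:

    S^0           = tok_emb[ids] + seg_emb[segments] + pos_emb[positions]
    O_i           = softmax(S W_i^Q (S W_i^K)^T / sqrt(l)) S W_i^V     per head
    M             = LN(S^{k-1} + [O_1; …; O_h] W^O)
    S^k           = LN(M + ReLU(M W_1 + b_1) W_2 + b_2)
    c             = W^pred s_cls

with l = d/h the per-head dimension and m = 4d the inner FFN width.  The
``literal`` architecture variant drops the post-concatenation projection
W^O and the FFN residual + layer norm, computing S^k = ReLU(M W_1 + b_1)
W_2 + b_2 directly.

Everything runs on CPU; a manual backward pass (`backward_batch`) provides
exact gradients for fine-tuning or from-scratch training, verified against
numerical differentiation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .pretreat import TokenSequence

_NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Hyperparameters of the k-stack, h-head encoder.

    The published full-scale configuration is k=12, h=12, d=768, m=3072
    (m = 4d); desk-scale models use the same structure at small k, h, d.
    """

    n_stacks: int = 2
    n_heads: int = 2
    d_model: int = 32
    n_max: int = 128
    vocab_size: int = 128
    n_classes: int = 2
    d_ff: int | None = None
    n_segments: int = 2
    layer_norm_eps: float = 1e-12
    dropout: float = 0.1
    architecture: str = "standard"  # "standard" | "literal"

    def __post_init__(self) -> None:
        if self.d_ff is None:
            self.d_ff = 4 * self.d_model
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.architecture not in ("standard", "literal"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if min(self.n_heads, self.d_model, self.n_max, self.vocab_size,
               self.n_classes, self.d_ff) < 1 or self.n_stacks < 0:
            raise ValueError("all dimensions must be positive")

    @property
    def head_dim(self) -> int:
        """Per-head dimension l = d / h."""
        return self.d_model // self.n_heads


def init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Randomly initialized parameters (N(0, 0.02) weights, unit LN gains)."""
    d, m = config.d_model, config.d_ff
    std = 0.02

    def w(*shape):
        return rng.normal(0.0, std, size=shape)

    params: dict[str, np.ndarray] = {
        "tok_emb": w(config.vocab_size, d),
        "seg_emb": w(config.n_segments, d),
        "pos_emb": w(config.n_max, d),
        "w_pred": w(config.n_classes, d),
    }
    for i in range(config.n_stacks):
        p = f"stack{i}."
        params[p + "wq"] = w(d, d)
        params[p + "wk"] = w(d, d)
        params[p + "wv"] = w(d, d)
        if config.architecture == "standard":
            params[p + "wo"] = w(d, d)
        params[p + "ln1_g"] = np.ones(d)
        params[p + "ln1_b"] = np.zeros(d)
        params[p + "w1"] = w(d, m)
        params[p + "b1"] = np.zeros(m)
        params[p + "w2"] = w(m, d)
        params[p + "b2"] = np.zeros(d)
        if config.architecture == "standard":
            params[p + "ln2_g"] = np.ones(d)
            params[p + "ln2_b"] = np.zeros(d)
    return params


def parameter_count(params: Mapping[str, np.ndarray]) -> int:
    return int(sum(v.size for v in params.values()))


# primitives -----------------------------------------------------------------


def _layer_norm(x: np.ndarray, g: np.ndarray, b: np.ndarray, eps: float):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv_std
    return g * xhat + b, (xhat, inv_std, g)


def _layer_norm_backward(dy: np.ndarray, cache):
    xhat, inv_std, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv_std * (dxhat - m1 - xhat * m2)
    return dx, dg, db


def _softmax(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=-1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=-1, keepdims=True)


def _split_heads(x: np.ndarray, h: int) -> np.ndarray:
    b, n, d = x.shape
    return x.reshape(b, n, h, d // h).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    b, h, n, l = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, n, h * l)


def _dropout_mask(shape, rate: float, rng: np.random.Generator | None):
    if rng is None or rate <= 0.0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


# batched forward / backward -------------------------------------------------


def forward_batch(
    ids: np.ndarray,
    seg: np.ndarray,
    mask: np.ndarray,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    rng: np.random.Generator | None = None,
):
    """Run the encoder on a batch; returns ([CLS] class scores, cache).

    ``ids``/``seg``/``mask`` are (B, n) integer arrays; ``mask`` is 1 on
    real tokens.  Padded key positions are excluded from every attention
    softmax, so appending padding never changes the [CLS] scores.  Passing
    ``rng`` enables (inverted) dropout for training.
    """
    if ids.ndim != 2:
        raise ValueError("ids must be a (batch, length) array")
    b, n = ids.shape
    if n > config.n_max:
        raise ValueError(f"sequence length {n} exceeds n_max {config.n_max}")
    if ids.max() >= config.vocab_size or ids.min() < 0:
        raise ValueError("token id out of vocabulary range")
    h, l = config.n_heads, config.head_dim
    scale = 1.0 / np.sqrt(l)
    key_bias = (1 - mask)[:, None, None, :] * _NEG_INF  # (B,1,1,n)

    s = params["tok_emb"][ids] + params["seg_emb"][seg] + params["pos_emb"][:n]
    emb_drop = _dropout_mask(s.shape, config.dropout, rng)
    if emb_drop is not None:
        s = s * emb_drop
    cache: dict = {"ids": ids, "seg": seg, "mask": mask, "emb_drop": emb_drop,
                   "s0": s, "stacks": []}

    for i in range(config.n_stacks):
        p = f"stack{i}."
        q = _split_heads(s @ params[p + "wq"], h)
        k = _split_heads(s @ params[p + "wk"], h)
        v = _split_heads(s @ params[p + "wv"], h)
        logits = q @ k.transpose(0, 1, 3, 2) * scale + key_bias
        attn = _softmax(logits)
        ctx = _merge_heads(attn @ v)  # (B,n,d) — O = [o_1;…;o_h]
        if config.architecture == "standard":
            attn_out = ctx @ params[p + "wo"]
        else:
            attn_out = ctx
        attn_drop = _dropout_mask(attn_out.shape, config.dropout, rng)
        if attn_drop is not None:
            attn_out = attn_out * attn_drop
        m_pre = s + attn_out
        m_post, ln1 = _layer_norm(m_pre, params[p + "ln1_g"], params[p + "ln1_b"],
                                  config.layer_norm_eps)
        hidden = m_post @ params[p + "w1"] + params[p + "b1"]
        relu = np.maximum(hidden, 0.0)
        ffn_out = relu @ params[p + "w2"] + params[p + "b2"]
        ffn_drop = _dropout_mask(ffn_out.shape, config.dropout, rng)
        if ffn_drop is not None:
            ffn_out = ffn_out * ffn_drop
        if config.architecture == "standard":
            s_out, ln2 = _layer_norm(m_post + ffn_out, params[p + "ln2_g"],
                                     params[p + "ln2_b"], config.layer_norm_eps)
        else:
            s_out, ln2 = ffn_out, None
        cache["stacks"].append({
            "s_in": s, "q": q, "k": k, "v": v, "attn": attn, "ctx": ctx,
            "attn_drop": attn_drop, "ln1": ln1, "m_post": m_post,
            "hidden": hidden, "relu": relu, "ffn_drop": ffn_drop, "ln2": ln2,
        })
        s = s_out

    cache["s_final"] = s
    scores = s[:, 0, :] @ params["w_pred"].T
    return scores, cache


def backward_batch(
    dscores: np.ndarray,
    cache: dict,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss wrt every parameter, given d loss/d scores."""
    h, l = config.n_heads, config.head_dim
    scale = 1.0 / np.sqrt(l)
    grads: dict[str, np.ndarray] = {}

    grads["w_pred"] = dscores.T @ cache["s_final"][:, 0, :]
    ds = np.zeros_like(cache["s_final"])
    ds[:, 0, :] = dscores @ params["w_pred"]

    for i in reversed(range(config.n_stacks)):
        p = f"stack{i}."
        c = cache["stacks"][i]
        m_post, relu, hidden = c["m_post"], c["relu"], c["hidden"]
        b, n, d = m_post.shape

        if config.architecture == "standard":
            dsum, dg2, db2_ln = _layer_norm_backward(ds, c["ln2"])
            grads[p + "ln2_g"], grads[p + "ln2_b"] = dg2, db2_ln
            dm = dsum.copy()
            dffn = dsum
        else:
            dm = np.zeros_like(m_post)
            dffn = ds
        if c["ffn_drop"] is not None:
            dffn = dffn * c["ffn_drop"]
        relu_flat = relu.reshape(-1, relu.shape[-1])
        dffn_flat = dffn.reshape(-1, d)
        grads[p + "w2"] = relu_flat.T @ dffn_flat
        grads[p + "b2"] = dffn_flat.sum(axis=0)
        drelu = dffn @ params[p + "w2"].T
        dhidden = drelu * (hidden > 0)
        m_flat = m_post.reshape(-1, d)
        dhidden_flat = dhidden.reshape(-1, dhidden.shape[-1])
        grads[p + "w1"] = m_flat.T @ dhidden_flat
        grads[p + "b1"] = dhidden_flat.sum(axis=0)
        dm = dm + dhidden @ params[p + "w1"].T

        dm_pre, dg1, db1_ln = _layer_norm_backward(dm, c["ln1"])
        grads[p + "ln1_g"], grads[p + "ln1_b"] = dg1, db1_ln
        ds_in = dm_pre.copy()
        dattn_out = dm_pre
        if c["attn_drop"] is not None:
            dattn_out = dattn_out * c["attn_drop"]
        if config.architecture == "standard":
            ctx_flat = c["ctx"].reshape(-1, d)
            grads[p + "wo"] = ctx_flat.T @ dattn_out.reshape(-1, d)
            dctx = dattn_out @ params[p + "wo"].T
        else:
            dctx = dattn_out
        dctx_h = _split_heads(dctx, h)  # (B,h,n,l)
        attn, q, k, v = c["attn"], c["q"], c["k"], c["v"]
        dattn = dctx_h @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx_h
        dlogits = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dq = dlogits @ k * scale
        dk = dlogits.transpose(0, 1, 3, 2) @ q * scale
        s_in_flat = c["s_in"].reshape(-1, d)
        for name, dmat in (("wq", dq), ("wk", dk), ("wv", dv)):
            dflat = _merge_heads(dmat).reshape(-1, d)
            grads[p + name] = s_in_flat.T @ dflat
            ds_in = ds_in + (dflat @ params[p + name].T).reshape(b, n, d)
        ds = ds_in

    if cache["emb_drop"] is not None:
        ds = ds * cache["emb_drop"]
    ids, seg = cache["ids"], cache["seg"]
    n = ids.shape[1]
    grads["tok_emb"] = np.zeros_like(params["tok_emb"])
    np.add.at(grads["tok_emb"], ids, ds)
    grads["seg_emb"] = np.zeros_like(params["seg_emb"])
    np.add.at(grads["seg_emb"], seg, ds)
    grads["pos_emb"] = np.zeros_like(params["pos_emb"])
    grads["pos_emb"][:n] = ds.sum(axis=0)
    return grads


# single-sequence operations -------------------------------------------------


def embed(seq: TokenSequence, params: Mapping[str, np.ndarray]) -> np.ndarray:
    """Input representation S^0: sum of token, segment and position embeddings."""
    ids = np.asarray(seq.ids)
    if ids.max() >= params["tok_emb"].shape[0] or ids.min() < 0:
        raise ValueError("token id out of vocabulary range")
    return (params["tok_emb"][ids] + params["seg_emb"][np.asarray(seq.segment_ids)]
            + params["pos_emb"][: len(ids)])


def attention_head(
    s: np.ndarray,
    wq: np.ndarray,
    wk: np.ndarray,
    wv: np.ndarray,
    mask: np.ndarray | None = None,
    return_attention: bool = False,
):
    """One scaled dot-product attention head: O = softmax(SW^Q (SW^K)^T/√l) SW^V.

    ``s`` is (n, d); the projections are (d, l).  Padded positions (mask 0)
    are removed from every softmax.
    """
    if not np.isfinite(s).all():
        raise ValueError("non-finite values in attention input")
    l = wq.shape[1]
    q, k, v = s @ wq, s @ wk, s @ wv
    logits = q @ k.T / np.sqrt(l)
    if mask is not None:
        logits = logits + (1 - np.asarray(mask))[None, :] * _NEG_INF
    attn = _softmax(logits)
    out = attn @ v
    return (out, attn) if return_attention else out


def _stack_prefix(stack_index: int) -> str:
    return f"stack{stack_index}."


def multi_head(
    s: np.ndarray,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    stack_index: int = 0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Multi-head attention sub-layer: M = LN(S + [O_1;…;O_h] W^O)."""
    p = _stack_prefix(stack_index)
    h, l = config.n_heads, config.head_dim
    outs = []
    for i in range(h):
        cols = slice(i * l, (i + 1) * l)
        outs.append(attention_head(s, params[p + "wq"][:, cols],
                                   params[p + "wk"][:, cols],
                                   params[p + "wv"][:, cols], mask=mask))
    o = np.concatenate(outs, axis=-1)
    if config.architecture == "standard":
        o = o @ params[p + "wo"]
    m, _ = _layer_norm(s + o, params[p + "ln1_g"], params[p + "ln1_b"],
                       config.layer_norm_eps)
    return m


def ffn(
    m: np.ndarray,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    stack_index: int = 0,
) -> np.ndarray:
    """Position-wise feed-forward sub-layer, ReLU(M W_1 + b_1) W_2 + b_2.

    The standard architecture wraps it in a residual connection and layer
    norm; the literal variant returns the two-layer network output directly.
    """
    p = _stack_prefix(stack_index)
    out = np.maximum(m @ params[p + "w1"] + params[p + "b1"], 0.0) @ params[p + "w2"] \
        + params[p + "b2"]
    if config.architecture == "standard":
        out, _ = _layer_norm(m + out, params[p + "ln2_g"], params[p + "ln2_b"],
                             config.layer_norm_eps)
    return out


def forward(
    seq: TokenSequence,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
) -> np.ndarray:
    """Class scores c = W^pred s_cls for one token sequence (no dropout)."""
    scores, _ = forward_batch(
        np.asarray(seq.ids)[None, :], np.asarray(seq.segment_ids)[None, :],
        np.asarray(seq.mask)[None, :], params, config, rng=None,
    )
    return scores[0]


def predict_proba_scores(scores: np.ndarray) -> np.ndarray:
    """Softmax over class scores (last axis)."""
    return _softmax(scores)


def export_attention(
    seq: TokenSequence,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    stack_index: int,
) -> np.ndarray:
    """Row-softmax attention matrices (h, n, n) of every head at one stack."""
    if not (0 <= stack_index < config.n_stacks):
        raise IndexError(f"stack index {stack_index} out of range "
                         f"[0, {config.n_stacks})")
    _, cache = forward_batch(
        np.asarray(seq.ids)[None, :], np.asarray(seq.segment_ids)[None, :],
        np.asarray(seq.mask)[None, :], params, config, rng=None,
    )
    return cache["stacks"][stack_index]["attn"][0]


# weight archives ------------------------------------------------------------


def save_params(params: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write a flat named-tensor archive (NumPy .npz, one entry per tensor)."""
    np.savez(path, **params)


def load_pretrained(
    path: str | Path,
    config: ModelConfig,
    name_map: Mapping[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Load externally converted weights into a ModelParams dict.

    ``name_map`` translates archive tensor names to this package's schema
    (``tok_emb``, ``stack{i}.wq`` …).  Missing or shape-mismatched tensors
    raise with the offending names listed; archive tensors that map to
    nothing are reported on the returned dict's side quietly (they are
    simply unused).
    """
    with np.load(path) as archive:
        raw = {k: archive[k] for k in archive.files}
    if name_map:
        raw = {name_map.get(k, k): v for k, v in raw.items()}
    reference = init_params(config, np.random.default_rng(0))
    missing = [k for k in reference if k not in raw]
    if missing:
        raise ValueError(f"weight archive lacks tensors: {sorted(missing)}")
    mismatched = [
        f"{k} (archive {raw[k].shape}, expected {reference[k].shape})"
        for k in reference
        if raw[k].shape != reference[k].shape
    ]
    if mismatched:
        raise ValueError(f"shape mismatch for tensors: {mismatched}")
    unused = sorted(set(raw) - set(reference))
    if unused:
        import logging

        logging.getLogger(__name__).info("unmapped archive tensors: %s", unused)
    return {k: np.asarray(raw[k], dtype=np.float64) for k in reference}
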