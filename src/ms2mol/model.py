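"""Encoder–decoder transformer for peaks-to-SMILES translation, in NumPy.

The spectrum-to-structure problem is cast as sequence translation: the
source sentence is a list of up to 100 integer m/z bin tokens (0.01-Da
bins over 0-500 Da) and the target sentence a SMILES token sequence.  The
architecture is the standard transformer: an embedding table over the
50,000 bin indices (plus one padding row), fixed sinusoidal positions,
multi-head attention with a causal mask on the decoder, position-wise
feed-forward sublayers, and an untied output projection onto the SMILES
vocabulary.

Everything — forward pass, backpropagation, the Adam optimizer and the
inverse-square-root warmup schedule — is implemented here directly on
NumPy arrays.  The full-scale configuration (12+12 layers, width 1024)
is fully describable and countable; training is exercised at widths where
a CPU is sufficient.  Prediction is stochastic: the model is decoded many
times with multinomial sampling, and the spread of the resulting unique
canonical SMILES doubles as a certainty signal.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ms2mol.chem import (
    MolecularFormula,
    PpmTolerance,
    PROTON_MASS,
    canonicalize,
    formula_of,
    monoisotopic_mass,
    ppm_window,
)
from ms2mol.codec import BinnedSpectrum
from ms2mol.dataset import TrainingSample, Vocabulary, default_vocabulary, detokenize

_NEG = np.float32(-1e9)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults are the full-scale model."""

    n_encoder_layers: int = 12
    n_decoder_layers: int = 12
    model_width: int = 1024
    n_heads: int = 16
    ff_width: int = 4096
    dropout: float = 0.20
    input_vocab: int = 50_001  # 50,000 bin tokens + 1 padding row
    output_vocab: int = 69
    max_input_len: int = 100
    max_output_len: int = 150

    def __post_init__(self) -> None:
        if self.model_width % self.n_heads != 0:
            raise ValueError("model_width must be divisible by n_heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def src_pad_id(self) -> int:
        return self.input_vocab - 1


def toy_model_config(**overrides) -> ModelConfig:
    """A small configuration trainable on one CPU in minutes."""
    base = dict(
        n_encoder_layers=2,
        n_decoder_layers=2,
        model_width=64,
        n_heads=4,
        ff_width=128,
        dropout=0.0,
        input_vocab=50_001,
        output_vocab=69,
        max_input_len=100,
        max_output_len=120,
    )
    base.update(overrides)
    return ModelConfig(**base)


def count_parameters_config(config: ModelConfig) -> int:
    """Closed-form trainable parameter count for a configuration.

    Embeddings + per-layer attention/feed-forward/normalisation terms +
    final stack norms + untied output projection.  Sinusoidal positions
    contribute nothing.
    """
    d, ff = config.model_width, config.ff_width
    attn = 4 * (d * d + d)            # Wq, Wk, Wv, Wo with biases
    ffn = d * ff + ff + ff * d + d    # two linear maps with biases
    ln = 2 * d                        # gamma + beta
    enc_layer = attn + ffn + 2 * ln
    dec_layer = 2 * attn + ffn + 3 * ln
    total = config.input_vocab * d          # source (bin) embedding
    total += config.output_vocab * d        # target embedding
    total += config.n_encoder_layers * enc_layer + ln   # + final encoder norm
    total += config.n_decoder_layers * dec_layer + ln   # + final decoder norm
    total += d * config.output_vocab + config.output_vocab  # projection
    return total


def sinusoidal_positions(length: int, width: int) -> np.ndarray:
    """Fixed sine/cosine positional code, shape (length, width)."""
    position = np.arange(length, dtype=np.float64)[:, None]
    div = np.exp(np.arange(0, width, 2, dtype=np.float64) * (-math.log(10000.0) / width))
    out = np.zeros((length, width), dtype=np.float64)
    out[:, 0::2] = np.sin(position * div)
    out[:, 1::2] = np.cos(position * div[: out[:, 1::2].shape[1]])
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# primitive ops (forward + backward)


def _layernorm_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    n = xhat.shape[-1]
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _linear_fwd(x, w, b):
    return x @ w + b, x


def _linear_bwd(dy, x, w):
    flat_x = x.reshape(-1, x.shape[-1])
    flat_dy = dy.reshape(-1, dy.shape[-1])
    dw = flat_x.T @ flat_dy
    db = flat_dy.sum(0)
    dx = dy @ w.T
    return dx, dw, db


def _softmax(x, axis=-1):
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def _split_heads(x, n_heads):
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    b, h, t, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)


def _mha_fwd(p, prefix, xq, xkv, key_mask, n_heads, causal):
    """Multi-head attention.  key_mask: (B, Tk) boolean, True = attendable."""
    q, _ = _linear_fwd(xq, p[prefix + "_wq"], p[prefix + "_bq"])
    k, _ = _linear_fwd(xkv, p[prefix + "_wk"], p[prefix + "_bk"])
    v, _ = _linear_fwd(xkv, p[prefix + "_wv"], p[prefix + "_bv"])
    qh, kh, vh = (_split_heads(t, n_heads) for t in (q, k, v))
    dh = qh.shape[-1]
    scores = qh @ kh.transpose(0, 1, 3, 2) / math.sqrt(dh)
    scores = np.where(key_mask[:, None, None, :], scores, _NEG)
    if causal:
        tq, tk = scores.shape[-2:]
        tri = np.triu(np.ones((tq, tk), dtype=bool), k=1)
        scores = np.where(tri[None, None], _NEG, scores)
    attn = _softmax(scores)
    ctx = _merge_heads(attn @ vh)
    out, _ = _linear_fwd(ctx, p[prefix + "_wo"], p[prefix + "_bo"])
    cache = (xq, xkv, qh, kh, vh, attn, ctx)
    return out, cache


def _mha_bwd(dy, p, prefix, cache, n_heads, grads):
    xq, xkv, qh, kh, vh, attn, ctx = cache
    dh = qh.shape[-1]
    dctx, dwo, dbo = _linear_bwd(dy, ctx, p[prefix + "_wo"])
    grads[prefix + "_wo"] += dwo
    grads[prefix + "_bo"] += dbo
    dctx_h = _split_heads(dctx, n_heads)
    dattn = dctx_h @ vh.transpose(0, 1, 3, 2)
    dvh = attn.transpose(0, 1, 3, 2) @ dctx_h
    dscores = attn * (dattn - (dattn * attn).sum(-1, keepdims=True))
    dscores /= math.sqrt(dh)
    dqh = dscores @ kh
    dkh = dscores.transpose(0, 1, 3, 2) @ qh
    dq, dk, dv = (_merge_heads(t) for t in (dqh, dkh, dvh))
    dxq, dwq, dbq = _linear_bwd(dq, xq, p[prefix + "_wq"])
    dxk, dwk, dbk = _linear_bwd(dk, xkv, p[prefix + "_wk"])
    dxv, dwv, dbv = _linear_bwd(dv, xkv, p[prefix + "_wv"])
    grads[prefix + "_wq"] += dwq
    grads[prefix + "_bq"] += dbq
    grads[prefix + "_wk"] += dwk
    grads[prefix + "_bk"] += dbk
    grads[prefix + "_wv"] += dwv
    grads[prefix + "_bv"] += dbv
    return dxq, dxk + dxv


def _ffn_fwd(p, prefix, x):
    h_pre, _ = _linear_fwd(x, p[prefix + "_w1"], p[prefix + "_b1"])
    h = np.maximum(h_pre, 0.0)
    out, _ = _linear_fwd(h, p[prefix + "_w2"], p[prefix + "_b2"])
    return out, (x, h_pre, h)


def _ffn_bwd(dy, p, prefix, cache, grads):
    x, h_pre, h = cache
    dh, dw2, db2 = _linear_bwd(dy, h, p[prefix + "_w2"])
    grads[prefix + "_w2"] += dw2
    grads[prefix + "_b2"] += db2
    dh_pre = dh * (h_pre > 0)
    dx, dw1, db1 = _linear_bwd(dh_pre, x, p[prefix + "_w1"])
    grads[prefix + "_w1"] += dw1
    grads[prefix + "_b1"] += db1
    return dx


def _dropout_fwd(x, rate, rng):
    if rate <= 0.0 or rng is None:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)
    return x * keep, keep


def _dropout_bwd(dy, keep):
    return dy if keep is None else dy * keep


# ---------------------------------------------------------------------------
# the model


class Seq2SeqTransformer:
    """Pre-norm encoder–decoder transformer over NumPy arrays."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, ff = config.model_width, config.ff_width
        p: Dict[str, np.ndarray] = {}

        def w(name, shape, scale=0.02):
            p[name] = (rng.standard_normal(shape) * scale).astype(np.float32)

        def zeros(name, shape):
            p[name] = np.zeros(shape, dtype=np.float32)

        def ln(prefix):
            p[prefix + "_g"] = np.ones(d, dtype=np.float32)
            zeros(prefix + "_b", d)

        def attn(prefix):
            for part in ("q", "k", "v", "o"):
                w(f"{prefix}_w{part}", (d, d))
                zeros(f"{prefix}_b{part}", d)

        def ffn(prefix):
            w(prefix + "_w1", (d, ff))
            zeros(prefix + "_b1", ff)
            w(prefix + "_w2", (ff, d))
            zeros(prefix + "_b2", d)

        w("emb_src", (config.input_vocab, d))
        p["emb_src"][config.src_pad_id] = 0.0
        w("emb_tgt", (config.output_vocab, d))
        for layer in range(config.n_encoder_layers):
            ln(f"enc{layer}_ln1")
            attn(f"enc{layer}_attn")
            ln(f"enc{layer}_ln2")
            ffn(f"enc{layer}_ff")
        ln("enc_lnf")
        for layer in range(config.n_decoder_layers):
            ln(f"dec{layer}_ln1")
            attn(f"dec{layer}_self")
            ln(f"dec{layer}_ln2")
            attn(f"dec{layer}_cross")
            ln(f"dec{layer}_ln3")
            ffn(f"dec{layer}_ff")
        ln("dec_lnf")
        w("proj_w", (d, config.output_vocab))
        zeros("proj_b", config.output_vocab)
        self.params = p
        self._pos = sinusoidal_positions(
            max(config.max_input_len, config.max_output_len) + 2, d
        )

    # -- forward -----------------------------------------------------------

    def encode(self, src_ids: np.ndarray, train: bool = False, rng=None):
        cfg, p = self.config, self.params
        mask = src_ids != cfg.src_pad_id
        x = p["emb_src"][src_ids] * math.sqrt(cfg.model_width)
        x = x + self._pos[: src_ids.shape[1]][None]
        x, keep0 = _dropout_fwd(x, cfg.dropout if train else 0.0, rng)
        caches = []
        for layer in range(cfg.n_encoder_layers):
            pre1, c_ln1 = _layernorm_fwd(x, p[f"enc{layer}_ln1_g"], p[f"enc{layer}_ln1_b"])
            a, c_attn = _mha_fwd(p, f"enc{layer}_attn", pre1, pre1, mask, cfg.n_heads, False)
            a, keep_a = _dropout_fwd(a, cfg.dropout if train else 0.0, rng)
            x = x + a
            pre2, c_ln2 = _layernorm_fwd(x, p[f"enc{layer}_ln2_g"], p[f"enc{layer}_ln2_b"])
            f_out, c_ff = _ffn_fwd(p, f"enc{layer}_ff", pre2)
            f_out, keep_f = _dropout_fwd(f_out, cfg.dropout if train else 0.0, rng)
            x = x + f_out
            caches.append((c_ln1, c_attn, keep_a, c_ln2, c_ff, keep_f))
        memory, c_lnf = _layernorm_fwd(x, p["enc_lnf_g"], p["enc_lnf_b"])
        return memory, (src_ids, mask, keep0, caches, c_lnf)

    def decode(
        self,
        tgt_in: np.ndarray,
        memory: np.ndarray,
        src_mask: np.ndarray,
        train: bool = False,
        rng=None,
    ):
        cfg, p = self.config, self.params
        pad = 3  # <pad> id in the target vocabulary
        tgt_mask = tgt_in != pad
        x = p["emb_tgt"][tgt_in] * math.sqrt(cfg.model_width)
        x = x + self._pos[: tgt_in.shape[1]][None]
        x, keep0 = _dropout_fwd(x, cfg.dropout if train else 0.0, rng)
        caches = []
        for layer in range(cfg.n_decoder_layers):
            pre1, c_ln1 = _layernorm_fwd(x, p[f"dec{layer}_ln1_g"], p[f"dec{layer}_ln1_b"])
            a, c_self = _mha_fwd(p, f"dec{layer}_self", pre1, pre1, tgt_mask, cfg.n_heads, True)
            a, keep_a = _dropout_fwd(a, cfg.dropout if train else 0.0, rng)
            x = x + a
            pre2, c_ln2 = _layernorm_fwd(x, p[f"dec{layer}_ln2_g"], p[f"dec{layer}_ln2_b"])
            c, c_cross = _mha_fwd(p, f"dec{layer}_cross", pre2, memory, src_mask, cfg.n_heads, False)
            c, keep_c = _dropout_fwd(c, cfg.dropout if train else 0.0, rng)
            x = x + c
            pre3, c_ln3 = _layernorm_fwd(x, p[f"dec{layer}_ln3_g"], p[f"dec{layer}_ln3_b"])
            f_out, c_ff = _ffn_fwd(p, f"dec{layer}_ff", pre3)
            f_out, keep_f = _dropout_fwd(f_out, cfg.dropout if train else 0.0, rng)
            x = x + f_out
            caches.append(
                (c_ln1, c_self, keep_a, c_ln2, c_cross, keep_c, c_ln3, c_ff, keep_f)
            )
        final, c_lnf = _layernorm_fwd(x, p["dec_lnf_g"], p["dec_lnf_b"])
        logits, _ = _linear_fwd(final, p["proj_w"], p["proj_b"])
        return logits, (tgt_in, tgt_mask, keep0, caches, c_lnf, final)

    def forward(self, src_ids, tgt_in, train=False, rng=None):
        memory, enc_cache = self.encode(src_ids, train, rng)
        logits, dec_cache = self.decode(
            tgt_in, memory, enc_cache[1], train, rng
        )
        return logits, (memory, enc_cache, dec_cache)

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits, caches) -> Dict[str, np.ndarray]:
        cfg, p = self.config, self.params
        memory, enc_cache, dec_cache = caches
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        # decoder
        tgt_in, tgt_mask, keep0, layer_caches, c_lnf, final_in = dec_cache
        dfinal, dproj_w, dproj_b = _linear_bwd(dlogits, c_lnf[0] * p["dec_lnf_g"] + p["dec_lnf_b"], p["proj_w"])
        # NB the linear input was the normalized activations; recompute via cache
        grads["proj_w"] += dproj_w
        grads["proj_b"] += dproj_b
        dx, dg, db = _layernorm_bwd(dfinal, c_lnf)
        grads["dec_lnf_g"] += dg
        grads["dec_lnf_b"] += db
        dmemory = np.zeros_like(memory)
        src_mask = enc_cache[1]
        for layer in reversed(range(cfg.n_decoder_layers)):
            c_ln1, c_self, keep_a, c_ln2, c_cross, keep_c, c_ln3, c_ff, keep_f = (
                layer_caches[layer]
            )
            dff = _dropout_bwd(dx, keep_f)
            dpre3 = _ffn_bwd(dff, p, f"dec{layer}_ff", c_ff, grads)
            dres, dg, db = _layernorm_bwd(dpre3, c_ln3)
            grads[f"dec{layer}_ln3_g"] += dg
            grads[f"dec{layer}_ln3_b"] += db
            dx = dx + dres
            dcross = _dropout_bwd(dx, keep_c)
            dpre2, dmem = _mha_bwd(dcross, p, f"dec{layer}_cross", c_cross, cfg.n_heads, grads)
            dmemory += dmem
            dres, dg, db = _layernorm_bwd(dpre2, c_ln2)
            grads[f"dec{layer}_ln2_g"] += dg
            grads[f"dec{layer}_ln2_b"] += db
            dx = dx + dres
            dself = _dropout_bwd(dx, keep_a)
            dpre1_q, dpre1_kv = _mha_bwd(dself, p, f"dec{layer}_self", c_self, cfg.n_heads, grads)
            dres, dg, db = _layernorm_bwd(dpre1_q + dpre1_kv, c_ln1)
            grads[f"dec{layer}_ln1_g"] += dg
            grads[f"dec{layer}_ln1_b"] += db
            dx = dx + dres
        dx = _dropout_bwd(dx, keep0)
        demb = dx * math.sqrt(cfg.model_width)
        np.add.at(grads["emb_tgt"], tgt_in, demb)

        # encoder
        src_ids, src_mask, keep0e, enc_layer_caches, c_lnf_e = enc_cache
        dx, dg, db = _layernorm_bwd(dmemory, c_lnf_e)
        grads["enc_lnf_g"] += dg
        grads["enc_lnf_b"] += db
        for layer in reversed(range(cfg.n_encoder_layers)):
            c_ln1, c_attn, keep_a, c_ln2, c_ff, keep_f = enc_layer_caches[layer]
            dff = _dropout_bwd(dx, keep_f)
            dpre2 = _ffn_bwd(dff, p, f"enc{layer}_ff", c_ff, grads)
            dres, dg, db = _layernorm_bwd(dpre2, c_ln2)
            grads[f"enc{layer}_ln2_g"] += dg
            grads[f"enc{layer}_ln2_b"] += db
            dx = dx + dres
            dattn = _dropout_bwd(dx, keep_a)
            dpre1_q, dpre1_kv = _mha_bwd(dattn, p, f"enc{layer}_attn", c_attn, cfg.n_heads, grads)
            dres, dg, db = _layernorm_bwd(dpre1_q + dpre1_kv, c_ln1)
            grads[f"enc{layer}_ln1_g"] += dg
            grads[f"enc{layer}_ln1_b"] += db
            dx = dx + dres
        dx = _dropout_bwd(dx, keep0e)
        demb = dx * math.sqrt(cfg.model_width)
        np.add.at(grads["emb_src"], src_ids, demb)
        grads["emb_src"][cfg.src_pad_id] = 0.0
        return grads


def build_model(config: ModelConfig, seed: int = 0) -> Seq2SeqTransformer:
    """Instantiate a model with freshly initialised weights."""
    return Seq2SeqTransformer(config, seed=seed)


def count_parameters(model: Seq2SeqTransformer) -> int:
    """Exact trainable scalar count of an instantiated model."""
    return int(sum(v.size for v in model.params.values()))


# ---------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and loop settings.

    The learning rate follows the inverse-square-root schedule
    ``scale * width^-0.5 * min(step^-0.5, step * warmup^-1.5)`` with the
    scale factor linear in batch_size / base_batch_size.
    """

    batch_size: int = 896
    beta1: float = 0.9
    beta2: float = 0.98
    eps: float = 1e-9
    warmup_steps: int = 8000
    base_batch_size: int = 896
    model_width: int = 1024
    patience: int = 10
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup_steps < 1:
            raise ValueError("warmup_steps must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def lr_schedule(step: int, config: TrainConfig) -> float:
    """Warmup-then-decay learning rate at a (1-based) optimizer step."""
    if step < 1:
        raise ValueError("step must be >= 1")
    factor = config.batch_size / config.base_batch_size
    return (
        factor
        * config.model_width ** -0.5
        * min(step ** -0.5, step * config.warmup_steps ** -1.5)
    )


@dataclass
class Checkpoint:
    """Best-validation weights plus the loss history that selected them."""

    params: Dict[str, np.ndarray]
    model_config: ModelConfig
    train_config: TrainConfig
    history: List[Tuple[int, float, float]]  # (epoch, train loss, val loss)
    best_epoch: int
    best_val_loss: float


def _pad_batch(
    samples: Sequence[TrainingSample], config: ModelConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    pad_tgt = 3
    src_len = max(max((len(s.input.bins) for s in samples), default=1), 1)
    tgt_len = max(len(s.target) for s in samples)
    src = np.full((len(samples), src_len), config.src_pad_id, dtype=np.int64)
    tgt_in = np.full((len(samples), tgt_len - 1), pad_tgt, dtype=np.int64)
    tgt_out = np.full((len(samples), tgt_len - 1), pad_tgt, dtype=np.int64)
    for row, s in enumerate(samples):
        bins = s.input.bins
        src[row, : len(bins)] = bins
        t = np.asarray(s.target, dtype=np.int64)
        tgt_in[row, : len(t) - 1] = t[:-1]
        tgt_out[row, : len(t) - 1] = t[1:]
    return src, tgt_in, tgt_out


def _cross_entropy(logits: np.ndarray, targets: np.ndarray, pad: int = 3):
    """Mean nats/token over non-pad positions; returns (loss, dlogits)."""
    probs = _softmax(logits.astype(np.float64))
    mask = targets != pad
    n = int(mask.sum())
    if n == 0:
        raise ValueError("batch contains no target tokens")
    rows = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
    loss = -float(np.log(np.maximum(rows, 1e-30))[mask].sum()) / n
    dlogits = probs
    np.put_along_axis(
        dlogits, targets[..., None],
        np.take_along_axis(dlogits, targets[..., None], axis=-1) - 1.0, axis=-1
    )
    dlogits *= (mask[..., None] / n)
    return loss, dlogits.astype(np.float32)


def evaluate_loss(model: Seq2SeqTransformer, dataset: Sequence[TrainingSample],
                  batch_size: int = 64) -> float:
    """Token-weighted cross-entropy of a dataset under the current weights."""
    total, count = 0.0, 0
    for start in range(0, len(dataset), batch_size):
        batch = dataset[start : start + batch_size]
        src, tgt_in, tgt_out = _pad_batch(batch, model.config)
        logits, _ = model.forward(src, tgt_in, train=False)
        mask = tgt_out != 3
        n = int(mask.sum())
        loss, _ = _cross_entropy(logits, tgt_out)
        total += loss * n
        count += n
    return total / count


def train(
    model: Seq2SeqTransformer,
    train_set: Sequence[TrainingSample],
    validation_set: Sequence[TrainingSample],
    config: TrainConfig,
) -> Checkpoint:
    """Fit with Adam under the warmup schedule; keep the best-validation
    weights; stop after ``patience`` epochs without improvement.

    Cross-entropy on next-token prediction with causal masking in the
    decoder and padding masking throughout.  Fully seeded: identical seeds
    give identical loss histories.  On return the model carries the
    best-validation weights.
    """
    if not train_set or not validation_set:
        raise ValueError("train and validation sets must be non-empty")
    vocab_size = model.config.output_vocab
    if any(max(s.target) >= vocab_size for s in train_set):
        raise ValueError("training targets exceed the model's output vocabulary")
    rng = np.random.default_rng(config.seed)
    drop_rng = np.random.default_rng(config.seed + 1)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    history: List[Tuple[int, float, float]] = []
    best_val = math.inf
    best_epoch = -1
    best_params: Optional[Dict[str, np.ndarray]] = None
    stale = 0
    indices = np.arange(len(train_set))
    for epoch in range(config.max_epochs):
        rng.shuffle(indices)
        epoch_loss, epoch_tokens = 0.0, 0
        for start in range(0, len(indices), config.batch_size):
            batch = [train_set[i] for i in indices[start : start + config.batch_size]]
            src, tgt_in, tgt_out = _pad_batch(batch, model.config)
            logits, caches = model.forward(src, tgt_in, train=True, rng=drop_rng)
            loss, dlogits = _cross_entropy(logits, tgt_out)
            grads = model.backward(dlogits, caches)
            step += 1
            lr = lr_schedule(step, config)
            b1, b2 = config.beta1, config.beta2
            for key, g in grads.items():
                m_state[key] = b1 * m_state[key] + (1 - b1) * g
                v_state[key] = b2 * v_state[key] + (1 - b2) * g * g
                mhat = m_state[key] / (1 - b1 ** step)
                vhat = v_state[key] / (1 - b2 ** step)
                model.params[key] -= lr * mhat / (np.sqrt(vhat) + config.eps)
            n_tok = int((tgt_out != 3).sum())
            epoch_loss += loss * n_tok
            epoch_tokens += n_tok
        val_loss = evaluate_loss(model, validation_set)
        history.append((epoch, epoch_loss / epoch_tokens, val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    assert best_params is not None
    model.params = best_params
    return Checkpoint(
        params=best_params,
        model_config=model.config,
        train_config=config,
        history=history,
        best_epoch=best_epoch,
        best_val_loss=best_val,
    )


# ---------------------------------------------------------------------------
# decoding and prediction sets


def _decode_step_batch(model, src, sample, rng=None, temperature=1.0,
                       max_len=None, vocab=None):
    """Autoregressive decode for a batch of sources; greedy or multinomial."""
    vocab = vocab or default_vocabulary()
    cfg = model.config
    max_len = max_len or cfg.max_output_len
    memory, enc_cache = model.encode(src, train=False)
    src_mask = enc_cache[1]
    b = src.shape[0]
    seqs = np.full((b, 1), vocab.sos_id, dtype=np.int64)
    finished = np.zeros(b, dtype=bool)
    for _ in range(max_len):
        logits, _ = model.decode(seqs, memory, src_mask, train=False)
        last = logits[:, -1, :]
        if sample:
            probs = _softmax(last.astype(np.float64) / temperature)
            cum = probs.cumsum(axis=-1)
            draw = rng.random((b, 1))
            nxt = (cum < draw).sum(axis=-1)
            nxt = np.minimum(nxt, probs.shape[-1] - 1)
        else:
            nxt = last.argmax(-1)
        nxt = np.where(finished, vocab.pad_id, nxt)
        seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
        finished |= nxt == vocab.eos_id
        if finished.all():
            break
    return [detokenize(seqs[i, 1:], vocab) for i in range(b)]


def greedy_decode(
    model: Seq2SeqTransformer,
    inputs: Sequence[BinnedSpectrum],
    vocab: Optional[Vocabulary] = None,
    batch_size: int = 64,
) -> List[str]:
    """Deterministic argmax decoding of each input spectrum to a SMILES."""
    vocab = vocab or default_vocabulary()
    out: List[str] = []
    for start in range(0, len(inputs), batch_size):
        chunk = inputs[start : start + batch_size]
        src_len = max(max(len(s.bins) for s in chunk), 1)
        src = np.full((len(chunk), src_len), model.config.src_pad_id, dtype=np.int64)
        for row, s in enumerate(chunk):
            src[row, : len(s.bins)] = s.bins
        out.extend(_decode_step_batch(model, src, sample=False, vocab=vocab))
    return out


@dataclass(frozen=True)
class PredictionSet:
    """Outputs of repeated stochastic decoding of one spectrum.

    ``unique_canonical`` tallies valid outputs after canonicalization; its
    frequencies plus ``n_invalid`` sum to ``n_runs``.  A low uniqueness
    ratio marks a confident model: when it "knows" the answer it repeats
    it, whereas an unsure model scatters across many unique strings.
    """

    raw_outputs: Tuple[str, ...]
    unique_canonical: Dict[str, int]
    n_invalid: int
    formula_filtered: Optional[Dict[str, int]] = None

    @property
    def n_runs(self) -> int:
        return len(self.raw_outputs)

    @property
    def uniqueness_ratio(self) -> float:
        return len(self.unique_canonical) / self.n_runs if self.n_runs else 0.0

    def most_frequent(self) -> Optional[str]:
        pool = self.formula_filtered if self.formula_filtered is not None else self.unique_canonical
        if not pool:
            return None
        return min(pool, key=lambda s: (-pool[s], s))


def sample_predictions(
    model: Seq2SeqTransformer,
    spectrum: BinnedSpectrum,
    n_runs: int = 100,
    seed: int = 0,
    temperature: float = 1.0,
    vocab: Optional[Vocabulary] = None,
) -> PredictionSet:
    """Decode one spectrum ``n_runs`` times with multinomial sampling.

    Invalid SMILES are discarded but counted; survivors are canonicalized
    and tallied.  Identical seeds give identical raw outputs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not spectrum.bins:
        raise ValueError("input spectrum is empty")
    vocab = vocab or default_vocabulary()
    rng = np.random.default_rng(seed)
    src = np.asarray([spectrum.bins] * n_runs, dtype=np.int64)
    raw = _decode_step_batch(
        model, src, sample=True, rng=rng, temperature=temperature, vocab=vocab
    )
    tally: Dict[str, int] = {}
    invalid = 0
    for text in raw:
        try:
            canonical = canonicalize(text)
        except Exception:
            invalid += 1
            continue
        tally[canonical] = tally.get(canonical, 0) + 1
    return PredictionSet(
        raw_outputs=tuple(raw), unique_canonical=tally, n_invalid=invalid
    )


def formula_filter(
    predictions: PredictionSet,
    precursor_mz: Optional[float] = None,
    tol: PpmTolerance = PpmTolerance(),
    target_formula: Optional[MolecularFormula] = None,
) -> PredictionSet:
    """Keep predictions compatible with the known molecular formula.

    With an explicit ``target_formula``, exact formula equality is
    required; otherwise a prediction passes when its protonated
    monoisotopic mass lies within the ppm window of ``precursor_mz``.  An
    empty result is meaningful: the model made no prediction with the
    correct formula.
    """
    if target_formula is None and precursor_mz is None:
        raise ValueError("supply either precursor_mz or target_formula")
    kept: Dict[str, int] = {}
    for smiles, freq in predictions.unique_canonical.items():
        f = formula_of(smiles)
        if target_formula is not None:
            ok = f == target_formula
        else:
            mz = monoisotopic_mass(f) + PROTON_MASS
            ok = abs(mz - precursor_mz) <= ppm_window(precursor_mz, tol)
        if ok:
            kept[smiles] = freq
    return replace(predictions, formula_filtered=kept)


def merge_prediction_sets(sets: Sequence[PredictionSet]) -> PredictionSet:
    """Union of prediction sets with summed frequencies (used by top-k)."""
    raw: List[str] = []
    tally: Dict[str, int] = {}
    filtered: Dict[str, int] = {}
    invalid = 0
    any_filtered = False
    for ps in sets:
        raw.extend(ps.raw_outputs)
        invalid += ps.n_invalid
        for s, f in ps.unique_canonical.items():
            tally[s] = tally.get(s, 0) + f
        if ps.formula_filtered is not None:
            any_filtered = True
            for s, f in ps.formula_filtered.items():
                filtered[s] = filtered.get(s, 0) + f
    return PredictionSet(
        raw_outputs=tuple(raw),
        unique_canonical=tally,
        n_invalid=invalid,
        formula_filtered=filtered if any_filtered else None,
    )
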