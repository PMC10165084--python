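"""Sparse-attention encoder-decoder for EEG channel completion.

The network maps windows of a few measured channels to the signal of one
unmeasured ("virtual" / complementary) channel.  Architecture:

* per-time-step linear value embedding of the ``d_x`` input channels into
  ``d_model`` dimensions, plus sinusoidal positional encoding whose base is
  ``2 * L_x`` (twice the encoder window length) rather than the customary
  10000 — positions never exceed the window, so the short base spreads the
  phases over the window;
* a 2-layer encoder of multi-head ProbSparse self-attention with a
  distilling step (1-D convolution, ELU, stride-2 max pooling) after each
  layer, halving the token count per layer (48 -> 24 -> 12 with defaults);
* a 1-layer generative decoder: causal masked self-attention over the label
  window, dense cross-attention to the encoder memory, and a linear head
  that emits the whole output window in a single pass (no autoregression).

ProbSparse attention scores every query by a sparsity measure
``M(q, K) = logsumexp_j(q k_j / sqrt(d)) - mean_j(q k_j / sqrt(d))`` and
computes full softmax attention only for the top-``u`` queries; the
remaining output rows are filled with the mean of the value rows.

Global timestamp embeddings (hour/day/week) are intentionally absent: the
model sees only within-window positions, which is what matters for
non-stationary EEG.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np

from .autograd import Parameter, Tensor

__all__ = [
    "ModelConfig",
    "CompletionInformer",
    "positional_encode",
    "encode_positions",
    "sparsity_measure",
    "probsparse_attention",
    "distill",
    "distilled_length",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the completion network.

    Defaults follow the reference configuration: embedding dimension 128,
    16 heads, 2 encoder layers, 1 decoder layer, encoder window 48 samples,
    decoder label window 24 samples, 4 input channels, 1 output channel,
    dropout 0.05.  ``sampling_factor`` controls how many queries receive
    full attention (``u = ceil(factor * ln L_Q)``).
    """

    d_model: int = 128
    n_heads: int = 16
    n_enc_layers: int = 2
    n_dec_layers: int = 1
    seq_len: int = 48
    label_len: int = 24
    d_x: int = 4
    d_y: int = 1
    d_ff: int | None = None
    dropout: float = 0.05
    sampling_factor: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.label_len > self.seq_len:
            raise ValueError("label_len must not exceed seq_len")
        if self.d_y != 1:
            raise ValueError("one complementary channel per model (d_y = 1)")
        for name in ("d_model", "n_heads", "n_enc_layers", "n_dec_layers",
                     "seq_len", "label_len", "d_x", "d_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def head_dim(self) -> int:
        return self.d_model // self.n_heads

    @property
    def hidden_ff(self) -> int:
        return self.d_ff if self.d_ff is not None else 4 * self.d_model


# ---------------------------------------------------------------------------
# Positional encoding
# ---------------------------------------------------------------------------

def encode_positions(positions: np.ndarray, L_x: int, d_model: int) -> np.ndarray:
    """Sinusoidal encoding of integer positions, base ``2 * L_x``.

    Component ``2j`` is ``sin(pos / (2 L_x)^(2j / d_model))`` and component
    ``2j + 1`` is the matching cosine; paired components therefore lie on
    the unit circle.
    """
    if d_model % 2 != 0:
        raise ValueError("d_model must be even for paired sin/cos components")
    positions = np.asarray(positions, dtype=float)
    j2 = np.arange(0, d_model, 2, dtype=float)  # 2j for pair index j = 0, 1, ...
    angles = positions[..., None] / (2.0 * L_x) ** (j2 / d_model)
    pe = np.empty(positions.shape + (d_model,))
    pe[..., 0::2] = np.sin(angles)
    pe[..., 1::2] = np.cos(angles)
    return pe


def positional_encode(pos: int, L_x: int, d_model: int) -> np.ndarray:
    """Encoding vector for one time index (see :func:`encode_positions`)."""
    if pos < 0:
        raise ValueError("pos must be non-negative")
    return encode_positions(np.array(float(pos)), L_x, d_model)


# ---------------------------------------------------------------------------
# ProbSparse attention primitives (plain-array reference forms)
# ---------------------------------------------------------------------------

def sparsity_measure(q: np.ndarray, K: np.ndarray, d: int | None = None) -> float:
    """Sparsity score of one query against a key set.

    ``M = logsumexp_j(q k_j / sqrt(d)) - mean_j(q k_j / sqrt(d))``; large
    values mean the query attends selectively.  ``M >= ln(L_K)`` always,
    with equality when all scores are equal.
    """
    q = np.asarray(q, dtype=float)
    K = np.asarray(K, dtype=float)
    if K.size == 0:
        raise ValueError("key set must be non-empty")
    if d is None:
        d = q.shape[-1]
    scores = K @ q / math.sqrt(d)
    m = scores.max()
    lse = m + math.log(np.exp(scores - m).sum())
    return float(lse - scores.mean())


def _sparsity_scores(
    Q: np.ndarray, K_sample: np.ndarray, scale: float
) -> np.ndarray:
    """Vectorized sparsity measure, batched over leading axes."""
    scores = (Q @ np.swapaxes(K_sample, -1, -2)) * scale
    m = scores.max(axis=-1, keepdims=True)
    lse = m[..., 0] + np.log(np.exp(scores - m).sum(axis=-1))
    return lse - scores.mean(axis=-1)


def default_top_u(L_Q: int, factor: float = 5.0) -> int:
    return min(L_Q, int(math.ceil(factor * math.log(L_Q)))) if L_Q > 1 else L_Q


def default_key_sample(L_K: int, L_Q: int) -> int:
    return min(L_K, int(math.ceil(L_K * math.log(L_Q)))) if L_Q > 1 else L_K


def probsparse_attention(
    Q: np.ndarray,
    K: np.ndarray,
    V: np.ndarray,
    u: int | None = None,
    key_sample: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """ProbSparse attention on plain 2-D arrays (reference form).

    Queries are ranked by :func:`sparsity_measure` computed over
    ``key_sample`` randomly chosen keys; the top-``u`` queries get full
    softmax attention ``softmax(Q̄ Kᵀ / sqrt(d)) V`` over *all* keys, and
    every other output row is the mean of the value rows.  With
    ``u = L_Q`` and ``key_sample = L_K`` this reduces exactly to dense
    attention.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    L_Q, d = Q.shape
    L_K = K.shape[0]
    if K.shape[1] != d or V.shape[0] != L_K:
        raise ValueError("Q, K, V dimensions are inconsistent")
    if u is None:
        u = default_top_u(L_Q)
    if key_sample is None:
        key_sample = default_key_sample(L_K, L_Q)
    if not (1 <= key_sample <= L_K):
        raise ValueError("key_sample must be in [1, L_K]")
    if not (0 <= u <= L_Q):
        raise ValueError("u must be in [0, L_Q]")

    scale = 1.0 / math.sqrt(d)
    if key_sample < L_K:
        if rng is None:
            rng = np.random.default_rng(0)
        ks = K[rng.choice(L_K, size=key_sample, replace=False)]
    else:
        ks = K
    M = _sparsity_scores(Q, ks, scale)

    out = np.broadcast_to(V.mean(axis=0), (L_Q, V.shape[1])).copy()
    if u > 0:
        top = np.argsort(-M, kind="stable")[:u]
        scores = (Q[top] @ K.T) * scale
        scores -= scores.max(axis=-1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=-1, keepdims=True)
        out[top] = w @ V
    return out


# ---------------------------------------------------------------------------
# Layers (autograd Tensors)
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class _Linear:
    def __init__(self, rng, d_in: int, d_out: int, prefix: str):
        self.W = Parameter(_glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out))
        self.names = {f"{prefix}.W": self.W, f"{prefix}.b": self.b}

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class _LayerNorm:
    def __init__(self, d: int, prefix: str, eps: float = 1e-5):
        self.g = Parameter(np.ones(d))
        self.b = Parameter(np.zeros(d))
        self.eps = eps
        self.names = {f"{prefix}.g": self.g, f"{prefix}.b": self.b}

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.g * (xc / (var + self.eps).sqrt()) + self.b


def _maximum(a: Tensor, b: Tensor) -> Tensor:
    return a + (b - a).relu()


class _MultiHeadAttention:
    """Multi-head attention; ProbSparse, dense, or causal-masked dense."""

    def __init__(self, rng, cfg: ModelConfig, prefix: str):
        d = cfg.d_model
        self.cfg = cfg
        self.Wq = Parameter(_glorot(rng, d, d))
        self.Wk = Parameter(_glorot(rng, d, d))
        self.Wv = Parameter(_glorot(rng, d, d))
        self.Wo = Parameter(_glorot(rng, d, d))
        self.names = {
            f"{prefix}.Wq": self.Wq,
            f"{prefix}.Wk": self.Wk,
            f"{prefix}.Wv": self.Wv,
            f"{prefix}.Wo": self.Wo,
        }

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        h, dh = self.cfg.n_heads, self.cfg.head_dim
        return x.reshape(B, L, h, dh).transpose(0, 2, 1, 3)  # (B, H, L, dh)

    def __call__(
        self,
        xq: Tensor,
        xkv: Tensor,
        mode: Literal["probsparse", "dense", "causal"],
        rng: np.random.Generator | None,
    ) -> Tensor:
        B, L_Q, _ = xq.shape
        L_K = xkv.shape[1]
        h, dh = self.cfg.n_heads, self.cfg.head_dim
        Q = self._split(xq @ self.Wq, B, L_Q)
        K = self._split(xkv @ self.Wk, B, L_K)
        V = self._split(xkv @ self.Wv, B, L_K)
        scale = 1.0 / math.sqrt(dh)

        if mode == "probsparse":
            out = self._probsparse(Q, K, V, scale, rng)
        else:
            scores = (Q @ K.swapaxes(-1, -2)) * scale
            if mode == "causal":
                mask = np.triu(np.full((L_Q, L_K), -1e9), k=1)
                scores = scores + Tensor(mask)
            out = scores.softmax(axis=-1) @ V
        out = out.transpose(0, 2, 1, 3).reshape(B, L_Q, h * dh)
        return out @ self.Wo

    def _probsparse(
        self,
        Q: Tensor,
        K: Tensor,
        V: Tensor,
        scale: float,
        rng: np.random.Generator | None,
    ) -> Tensor:
        B, H, L_Q, dh = Q.shape
        L_K = K.shape[2]
        u = default_top_u(L_Q, self.cfg.sampling_factor)
        n_sample = default_key_sample(L_K, L_Q)
        if n_sample < L_K and rng is not None:
            sel = rng.choice(L_K, size=n_sample, replace=False)
            k_sample = K.data[:, :, sel, :]
        else:
            k_sample = K.data
        M = _sparsity_scores(Q.data, k_sample, scale)  # (B, H, L_Q)
        top = np.argsort(-M, axis=-1, kind="stable")[..., :u]  # unique per (B, H)

        base = V.mean(axis=-2, keepdims=True) * Tensor(np.ones((L_Q, 1)))
        if u == 0:
            return base
        Q_top = Q.take_rows(top)  # (B, H, u, dh)
        attn = ((Q_top @ K.swapaxes(-1, -2)) * scale).softmax(axis=-1) @ V
        return base.set_rows(top, attn)


class _FeedForward:
    def __init__(self, rng, cfg: ModelConfig, prefix: str):
        self.fc1 = _Linear(rng, cfg.d_model, cfg.hidden_ff, f"{prefix}.fc1")
        self.fc2 = _Linear(rng, cfg.hidden_ff, cfg.d_model, f"{prefix}.fc2")
        self.names = {**self.fc1.names, **self.fc2.names}

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class _EncoderLayer:
    def __init__(self, rng, cfg: ModelConfig, prefix: str):
        self.cfg = cfg
        self.attn = _MultiHeadAttention(rng, cfg, f"{prefix}.attn")
        self.ffn = _FeedForward(rng, cfg, f"{prefix}.ffn")
        self.ln1 = _LayerNorm(cfg.d_model, f"{prefix}.ln1")
        self.ln2 = _LayerNorm(cfg.d_model, f"{prefix}.ln2")
        self.names = {**self.attn.names, **self.ffn.names, **self.ln1.names, **self.ln2.names}

    def __call__(self, x: Tensor, rng) -> Tensor:
        # pre-norm residual blocks: the un-normalized stream carries signal
        # amplitude straight through to the output head
        n = self.ln1(x)
        a = self.attn(n, n, "probsparse", rng)
        x = x + a.dropout(self.cfg.dropout, rng)
        f = self.ffn(self.ln2(x))
        return x + f.dropout(self.cfg.dropout, rng)


class _DistillLayer:
    """Conv1d (kernel 3, zero pad 1) -> ELU -> max pool (kernel 3, stride 2, pad 1)."""

    def __init__(self, rng, d_model: int, prefix: str):
        w = _glorot(rng, 3 * d_model, d_model, shape=(3, d_model, d_model))
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(d_model))
        self.names = {f"{prefix}.W": self.W, f"{prefix}.b": self.b}

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[1]
        if L < 2:
            raise ValueError("distilling needs sequence length >= 2")
        xp = x.pad_axis(1, 1, 1, 0.0)
        y = (
            xp[:, 0:L, :] @ self.W[0]
            + xp[:, 1 : L + 1, :] @ self.W[1]
            + xp[:, 2 : L + 2, :] @ self.W[2]
            + self.b
        ).elu()
        return _max_pool_half(y)


def _max_pool_half(y: Tensor) -> Tensor:
    """Max pooling along axis 1: kernel 3, stride 2, pad 1 -> ceil(L/2) steps."""
    L = y.shape[1]
    n_out = (L + 1) // 2
    # pad just below the data minimum: acts as -inf for the max without the
    # catastrophic cancellation a huge sentinel causes in a + relu(b - a)
    pad_val = float(y.data.min()) - 1.0
    yp = y.pad_axis(1, 1, 1, pad_val)
    s0 = yp[:, 0 : 2 * n_out - 1 : 2, :]
    s1 = yp[:, 1 : 2 * n_out : 2, :]
    s2 = yp[:, 2 : 2 * n_out + 1 : 2, :]
    return _maximum(_maximum(s0, s1), s2)


def distilled_length(L: int) -> int:
    """Sequence length after one distilling step: ``ceil(L / 2)``."""
    return (L + 1) // 2


def distill(
    X: np.ndarray, weight: np.ndarray | None = None, bias: np.ndarray | None = None
) -> np.ndarray:
    """Apply one distilling step to a plain (L, d_model) array.

    Without explicit weights the convolution defaults to the identity
    (centre tap = I), so the operation reduces to ELU + pooling; the model
    uses learned taps internally.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (L, d_model)")
    L, d = X.shape
    if L < 2:
        raise ValueError("distilling needs sequence length >= 2")
    if weight is None:
        weight = np.zeros((3, d, d))
        weight[1] = np.eye(d)
    if bias is None:
        bias = np.zeros(d)
    layer = _DistillLayer.__new__(_DistillLayer)
    layer.W = Tensor(weight)
    layer.b = Tensor(bias)
    return layer(Tensor(X[None])).data[0]


class _DecoderLayer:
    def __init__(self, rng, cfg: ModelConfig, prefix: str):
        self.cfg = cfg
        self.self_attn = _MultiHeadAttention(rng, cfg, f"{prefix}.self")
        self.cross_attn = _MultiHeadAttention(rng, cfg, f"{prefix}.cross")
        self.ffn = _FeedForward(rng, cfg, f"{prefix}.ffn")
        self.ln1 = _LayerNorm(cfg.d_model, f"{prefix}.ln1")
        self.ln2 = _LayerNorm(cfg.d_model, f"{prefix}.ln2")
        self.ln3 = _LayerNorm(cfg.d_model, f"{prefix}.ln3")
        self.names = {
            **self.self_attn.names,
            **self.cross_attn.names,
            **self.ffn.names,
            **self.ln1.names,
            **self.ln2.names,
            **self.ln3.names,
        }

    def __call__(self, x: Tensor, memory: Tensor, rng) -> Tensor:
        n = self.ln1(x)
        a = self.self_attn(n, n, "causal", rng)
        x = x + a.dropout(self.cfg.dropout, rng)
        c = self.cross_attn(self.ln2(x), memory, "dense", rng)
        x = x + c.dropout(self.cfg.dropout, rng)
        f = self.ffn(self.ln3(x))
        return x + f.dropout(self.cfg.dropout, rng)


class CompletionInformer:
    """The channel-completion network.

    ``forward`` takes an encoder window of the input channels, the decoder
    label window (a slice of the same input channels starting at offset
    ``t_s``), and the corresponding within-window positions; it returns the
    predicted target-channel values over the label window in one pass.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cfg = config
        self.enc_embed = _Linear(rng, cfg.d_x, cfg.d_model, "enc_embed")
        self.dec_embed = _Linear(rng, cfg.d_x, cfg.d_model, "dec_embed")
        self.enc_layers = [
            _EncoderLayer(rng, cfg, f"enc{i}") for i in range(cfg.n_enc_layers)
        ]
        self.distills = [
            _DistillLayer(rng, cfg.d_model, f"distill{i}")
            for i in range(cfg.n_enc_layers)
        ]
        self.dec_layers = [
            _DecoderLayer(rng, cfg, f"dec{i}") for i in range(cfg.n_dec_layers)
        ]
        self.head = _Linear(rng, cfg.d_model, cfg.d_y, "head")
        self.head.W.data[:] = 0.0  # zero-init output projection: the network
        # starts at the constant-zero map and grows the readout from data
        self._params: dict[str, Parameter] = {}
        for mod in (
            [self.enc_embed, self.dec_embed, self.head]
            + self.enc_layers
            + self.distills
            + self.dec_layers
        ):
            self._params.update(mod.names)

    # -- parameters -----------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        return list(self._params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self._params.values())

    # -- forward --------------------------------------------------------------
    def forward(
        self,
        enc_in: np.ndarray,
        dec_in: np.ndarray,
        enc_pos: np.ndarray | None = None,
        dec_pos: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Predict the label window; deterministic when ``rng`` is None."""
        out = self._forward_t(enc_in, dec_in, enc_pos, dec_pos, rng)
        return out.data if np.ndim(enc_in) == 3 else out.data[0]

    def _forward_t(
        self,
        enc_in,
        dec_in,
        enc_pos=None,
        dec_pos=None,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        cfg = self.config
        enc_in = np.asarray(enc_in, dtype=float)
        dec_in = np.asarray(dec_in, dtype=float)
        if enc_in.ndim == 2:
            enc_in, dec_in = enc_in[None], dec_in[None]
        if enc_in.shape[1:] != (cfg.seq_len, cfg.d_x):
            raise ValueError(
                f"encoder input must be (B, {cfg.seq_len}, {cfg.d_x}); got {enc_in.shape}"
            )
        if dec_in.shape[1:] != (cfg.label_len, cfg.d_x):
            raise ValueError(
                f"decoder input must be (B, {cfg.label_len}, {cfg.d_x}); got {dec_in.shape}"
            )
        if not (np.all(np.isfinite(enc_in)) and np.all(np.isfinite(dec_in))):
            raise ValueError("non-finite values in model input")
        if enc_pos is None:
            enc_pos = np.arange(cfg.seq_len)
        if dec_pos is None:
            dec_pos = np.arange(cfg.seq_len - cfg.label_len, cfg.seq_len)

        pe_enc = encode_positions(np.asarray(enc_pos), cfg.seq_len, cfg.d_model)
        pe_dec = encode_positions(np.asarray(dec_pos), cfg.seq_len, cfg.d_model)

        # map [0, 1] inputs to [-1, 1] so the value embedding is centred on the
        # same scale as the positional encoding
        enc_in = 2.0 * enc_in - 1.0
        dec_in = 2.0 * dec_in - 1.0

        x = (self.enc_embed(Tensor(enc_in)) + Tensor(pe_enc)).dropout(cfg.dropout, rng)
        for layer, dist in zip(self.enc_layers, self.distills):
            x = layer(x, rng)
            x = dist(x)
        memory = x

        y = (self.dec_embed(Tensor(dec_in)) + Tensor(pe_dec)).dropout(cfg.dropout, rng)
        for layer in self.dec_layers:
            y = layer(y, memory, rng)
        return self.head(y)

    def encoder_token_counts(self) -> list[int]:
        """Sequence length entering each encoder layer (the distilling law)."""
        counts = [self.config.seq_len]
        for _ in range(1, self.config.n_enc_layers):
            counts.append(distilled_length(counts[-1]))
        return counts

    # -- checkpointing ---------------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        """Write weights + config (+ optional JSON-serializable metadata)."""
        meta = {"config": asdict(self.config), "extra": extra or {}}
        arrays = {f"param:{k}": p.data for k, p in self._params.items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> tuple["CompletionInformer", dict]:
        with np.load(path) as archive:
            meta = json.loads(archive["__meta__"].tobytes().decode())
            model = cls(ModelConfig(**meta["config"]))
            for k, p in model._params.items():
                p.data = archive[f"param:{k}"].copy()
        return model, meta["extra"]
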