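"""Stage-2 sequence models over per-window embedding sequences.

The primary regressor runs a unidirectional two-layer GRU over the window
summary vectors, pools the top-layer hidden states with a dot-product
attention (softmax of w·h_t over real windows, no bias or temperature), and
feeds the resulting context vector to a linear head:

    {h_1..h_T} = GRU(CLS_1..CLS_T)
    alpha_t    = exp(w·h_t) / sum_k exp(w·h_k)
    c          = sum_t alpha_t h_t
    score      = v·c + b

Two ablation variants share the interface: an order-free FFN over the masked
mean of the window embeddings, and a 2-layer transformer encoder followed by
the same attention pooling. Pad rows never influence predictions or weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import EmbeddingSequence
from .nn import GRULayer, LayerNorm, Linear, Module, Tensor, dropout, masked_softmax, stack, uniform_init

__all__ = [
    "AggregatorConfig",
    "AttentionProfile",
    "attention_pool",
    "build_variant",
    "run_rnn",
    "RNNAggregator",
    "FFNAggregator",
    "TransformerAggregator",
]


@dataclass(frozen=True)
class AggregatorConfig:
    variant: str = "rnn"  # rnn | ffn | transformer
    input_dim: int = 32
    hidden: int = 256
    layers: int = 2
    ffn_hidden: tuple = (256, 128)
    tx_layers: int = 2
    tx_heads: int = 8
    tx_ffdim: int = 2048
    dropout: float = 0.1
    seed: int = 0


@dataclass
class AttentionProfile:
    """Normalized per-window attention weights; zeros exactly at pad rows."""

    transcript_id: str
    trait: str
    alpha: np.ndarray  # (max_segments,)
    mask: np.ndarray = field(default=None)

    def validate(self, atol: float = 1e-6):
        real = self.mask if self.mask is not None else self.alpha > 0
        assert np.all(self.alpha >= 0)
        assert np.all(self.alpha[~real] == 0.0)
        assert abs(self.alpha[real].sum() - 1.0) <= atol
        return self


def attention_pool(states: np.ndarray, w_attn: np.ndarray, mask=None):
    """Dot-product attention pooling over hidden states (numpy surface).

    Returns ``(alpha, context)`` where ``alpha`` sums to 1 over real rows and
    is exactly 0 at masked rows, and ``context = sum_t alpha_t h_t``.
    """
    states = np.asarray(states, dtype=np.float64)
    if mask is None:
        mask = np.ones(states.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("attention_pool: need at least one real window")
    logits = states @ np.asarray(w_attn, dtype=np.float64)
    if not np.all(np.isfinite(logits[mask])):
        raise ValueError("attention_pool: nonfinite logits")
    shift = logits[mask].max()
    e = np.where(mask, np.exp(np.where(mask, logits - shift, 0.0)), 0.0)
    alpha = e / e.sum()
    return alpha, alpha @ states


class RNNAggregator(Module):
    def __init__(self, config: AggregatorConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        d, H = config.input_dim, config.hidden
        self.gru_layers = [
            GRULayer(d if i == 0 else H, H, rng) for i in range(config.layers)
        ]
        self.w_attn = uniform_init(rng, (H, 1), H)
        self.head = Linear(H, 1, rng, zero_init=True)

    def _states(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        inp = x
        for layer in self.gru_layers:
            h = Tensor(np.zeros((B, layer.hidden)))
            outs = []
            for t in range(T):
                h_new = layer.step(inp[:, t, :], h)
                m = mask[:, t : t + 1].astype(np.float64)
                h = h_new * m + h * (1.0 - m)
                outs.append(h)
            inp = stack(outs, axis=1)  # (B, T, H)
        return inp

    def forward(self, x, mask: np.ndarray):
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] != self.config.input_dim:
            raise ValueError("embedding dim does not match aggregator config")
        if not mask.any(axis=1).all():
            raise ValueError("all-pad embedding sequence")
        states = self._states(x, mask)
        B, T, H = states.shape
        logits = (states @ self.w_attn).reshape(B, T)
        alpha = masked_softmax(logits, mask)
        c = (alpha.reshape(B, 1, T) @ states).reshape(B, H)
        pred = self.head(c).reshape(B)
        return pred, alpha


class FFNAggregator(Module):
    """Order-free ablation: masked mean of window embeddings -> MLP head."""

    def __init__(self, config: AggregatorConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        dims = (config.input_dim,) + tuple(config.ffn_hidden)
        self.hidden_layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.head = Linear(dims[-1], 1, rng, zero_init=True)

    def forward(self, x, mask: np.ndarray):
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] != self.config.input_dim:
            raise ValueError("embedding dim does not match aggregator config")
        if not mask.any(axis=1).all():
            raise ValueError("all-pad embedding sequence")
        m = mask.astype(np.float64)
        mean = (x * m[:, :, None]).sum(axis=1) / m.sum(axis=1, keepdims=True)
        h = mean
        for layer in self.hidden_layers:
            h = layer(h).relu()
        pred = self.head(h).reshape(x.shape[0])
        # no attention exists; report a uniform placeholder over real windows
        alpha = Tensor(m / m.sum(axis=1, keepdims=True))
        return pred, alpha


class _TransformerBlock(Module):
    def __init__(self, d: int, heads: int, ffdim: int, rng):
        self.heads = heads
        self.wq = uniform_init(rng, (d, d), d)
        self.wk = uniform_init(rng, (d, d), d)
        self.wv = uniform_init(rng, (d, d), d)
        self.wo = Linear(d, d, rng)
        self.ln1 = LayerNorm(d)
        self.ln2 = LayerNorm(d)
        self.ff1 = Linear(d, ffdim, rng)
        self.ff2 = Linear(ffdim, d, rng)

    def __call__(self, x: Tensor, mask: np.ndarray, p: float, rng, training: bool):
        B, T, d = x.shape
        h = self.heads
        dh = d // h
        q = (x @ self.wq).reshape(B, T, h, dh).swapaxes(1, 2)
        k = (x @ self.wk).reshape(B, T, h, dh).swapaxes(1, 2)
        v = (x @ self.wv).reshape(B, T, h, dh).swapaxes(1, 2)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        key_mask = np.broadcast_to(mask[:, None, None, :], (B, h, T, T))
        attn = masked_softmax(scores, key_mask)
        out = (attn @ v).swapaxes(1, 2).reshape(B, T, d)
        x = self.ln1(x + dropout(self.wo(out), p, rng, training))
        f = self.ff2(self.ff1(x).relu())
        return self.ln2(x + dropout(f, p, rng, training))


class TransformerAggregator(Module):
    def __init__(self, config: AggregatorConfig):
        if config.input_dim % config.tx_heads != 0:
            raise ValueError("input_dim must be divisible by tx_heads")
        rng = np.random.default_rng(config.seed)
        self.config = config
        d = config.input_dim
        self.blocks = [
            _TransformerBlock(d, config.tx_heads, config.tx_ffdim, rng)
            for _ in range(config.tx_layers)
        ]
        self.w_attn = uniform_init(rng, (d, 1), d)
        self.head = Linear(d, 1, rng, zero_init=True)
        self._drop_rng = np.random.default_rng(config.seed + 1)

    def forward(self, x, mask: np.ndarray):
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] != self.config.input_dim:
            raise ValueError("embedding dim does not match aggregator config")
        if not mask.any(axis=1).all():
            raise ValueError("all-pad embedding sequence")
        p = self.config.dropout
        for block in self.blocks:
            x = block(x, mask, p, self._drop_rng, self.training)
        B, T, d = x.shape
        logits = (x @ self.w_attn).reshape(B, T)
        alpha = masked_softmax(logits, mask)
        c = (alpha.reshape(B, 1, T) @ x).reshape(B, d)
        c = dropout(c, p, self._drop_rng, self.training)
        pred = self.head(c).reshape(B)
        return pred, alpha


def build_variant(config: AggregatorConfig) -> Module:
    if config.variant == "rnn":
        return RNNAggregator(config)
    if config.variant == "ffn":
        return FFNAggregator(config)
    if config.variant == "transformer":
        return TransformerAggregator(config)
    raise ValueError(f"unknown aggregator variant {config.variant!r}")


def run_rnn(model: RNNAggregator, embeds: EmbeddingSequence) -> np.ndarray:
    """Hidden states h_1..h_T (real windows only) of the top GRU layer."""
    if embeds.n_windows < 1:
        raise ValueError("run_rnn: embedding sequence has no real windows")
    states = model._states(
        Tensor(embeds.vectors[None, :, :]), embeds.mask[None, :]
    ).data[0]
    return states[embeds.mask]


def predict(model: Module, embeds: EmbeddingSequence, trait: str = "") -> tuple:
    """Eval-mode prediction for one transcript: (score, AttentionProfile)."""
    was_training = model.training
    model.eval()
    pred, alpha = model.forward(embeds.vectors[None, :, :], embeds.mask[None, :])
    if was_training:
        model.train()
    profile = AttentionProfile(
        transcript_id=embeds.transcript_id,
        trait=trait,
        alpha=alpha.data[0].copy(),
        mask=embeds.mask.copy(),
    )
    return float(pred.data[0]), profile
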