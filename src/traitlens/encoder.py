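"""Stage-1 segment encoder: fine-tune on windows, freeze, emit CLS summaries.

The built-in :class:`TinyEncoder` is the smallest architecture exhibiting the
CLS-summary mechanism of the full pipeline: a token embedding table, one
multi-head attention block queried from a learned start ("CLS") vector, and a
scalar regression head. Because the CLS output of a single self-attention
block depends only on the CLS query and the token keys/values, evaluating
attention at the CLS position alone is exact, not an approximation.

Any object exposing ``embed_dim`` and ``encode_windows(wset) ->
EmbeddingSequence`` satisfies the encoder contract downstream modules rely
on; an adapter around an external pretrained transformer plugs in the same
way (tokenize to ids, emit one summary vector per window).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import Adam, Module, Tensor, masked_softmax, uniform_init
from .windowing import WindowSet


@dataclass
class EmbeddingSequence:
    """Per-window summary vectors, the hand-off between the two stages."""

    transcript_id: str
    vectors: np.ndarray  # (max_segments, d); all-zero rows where mask is False
    mask: np.ndarray  # (max_segments,) bool

    @property
    def n_windows(self) -> int:
        return int(self.mask.sum())


class TinyEncoder(Module):
    def __init__(self, vocab_size: int, embed_dim: int = 32, n_heads: int = 2,
                 pad_token: int = 0, seed: int = 0):
        if embed_dim % n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        rng = np.random.default_rng(seed)
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.pad_token = pad_token
        self.frozen = False
        d = embed_dim
        self.emb = Tensor(rng.normal(0.0, 0.1, size=(vocab_size + 1, d)), requires_grad=True)
        self.cls = Tensor(rng.normal(0.0, 0.1, size=(d,)), requires_grad=True)
        self.wq = uniform_init(rng, (d, d), d)
        self.wk = uniform_init(rng, (d, d), d)
        self.wv = uniform_init(rng, (d, d), d)
        self.wo = uniform_init(rng, (d, d), d)
        self.bo = Tensor(np.zeros(d), requires_grad=True)
        # zero-init head: the untrained encoder predicts the target mean
        self.head_w = Tensor(np.zeros((d, 1)), requires_grad=True)
        self.head_b = Tensor(np.zeros(1), requires_grad=True)

    # -- forward passes ------------------------------------------------------
    # Two implementations of the same function: a graph-building one for
    # fine-tuning / continuous-flow training and a plain-numpy one for frozen
    # inference. test_encoder asserts they agree to float precision.

    def _check_tokens(self, tokens: np.ndarray):
        if tokens.max(initial=0) > self.vocab_size:
            raise ValueError("token id exceeds encoder vocabulary")
        if not (tokens != self.pad_token).any(axis=1).all():
            raise ValueError("window with no real tokens cannot be encoded")

    def forward_cls(self, tokens: np.ndarray) -> Tensor:
        """Graph forward: (B, w) int tokens -> (B, d) CLS summaries."""
        self._check_tokens(tokens)
        B, w = tokens.shape
        h, d = self.n_heads, self.embed_dim
        dh = d // h
        x = self.emb[tokens]  # (B, w, d)
        keys = (x @ self.wk).reshape(B, w, h, dh).swapaxes(1, 2)  # (B,h,w,dh)
        vals = (x @ self.wv).reshape(B, w, h, dh).swapaxes(1, 2)
        q = (self.cls.reshape(1, d) @ self.wq).reshape(h, dh, 1)
        scores = (keys @ q).reshape(B, h, w) * (1.0 / np.sqrt(dh))
        attn_mask = np.broadcast_to((tokens != self.pad_token)[:, None, :], (B, h, w))
        attn = masked_softmax(scores, attn_mask)
        ctx = (attn.reshape(B, h, 1, w) @ vals).reshape(B, d)
        return (ctx @ self.wo + self.bo).tanh()

    def forward_score(self, tokens: np.ndarray) -> Tensor:
        cls = self.forward_cls(tokens)
        return (cls @ self.head_w).reshape(-1) + self.head_b[0]

    def _np_cls(self, tokens: np.ndarray) -> np.ndarray:
        self._check_tokens(tokens)
        B, w = tokens.shape
        h, d = self.n_heads, self.embed_dim
        dh = d // h
        x = self.emb.data[tokens]
        keys = (x @ self.wk.data).reshape(B, w, h, dh).swapaxes(1, 2)
        vals = (x @ self.wv.data).reshape(B, w, h, dh).swapaxes(1, 2)
        q = (self.cls.data.reshape(1, d) @ self.wq.data).reshape(h, dh, 1)
        scores = (keys @ q).reshape(B, h, w) / np.sqrt(dh)
        real = (tokens != self.pad_token)[:, None, :]
        shift = np.max(np.where(real, scores, -np.inf), axis=-1, keepdims=True)
        e = np.exp((scores - shift) * real) * real
        attn = e / e.sum(axis=-1, keepdims=True)
        ctx = (attn.reshape(B, h, 1, w) @ vals).reshape(B, d)
        return np.tanh(ctx @ self.wo.data + self.bo.data)

    def _np_score(self, tokens: np.ndarray) -> np.ndarray:
        return (self._np_cls(tokens) @ self.head_w.data).reshape(-1) + self.head_b.data[0]

    # -- public surface ------------------------------------------------------

    def freeze(self) -> "TinyEncoder":
        self.frozen = True
        return self

    def encode_windows(self, wset: WindowSet) -> EmbeddingSequence:
        if wset.windows.shape[1] != wset.config.window_size:
            raise ValueError("window matrix width differs from configured window size")
        vectors = np.zeros((len(wset.mask), self.embed_dim))
        if wset.n_windows:
            vectors[wset.mask] = self._np_cls(wset.windows[wset.mask])
        return EmbeddingSequence(wset.transcript_id, vectors, wset.mask.copy())

    def window_predictions(self, wset: WindowSet) -> np.ndarray:
        """Scalar head applied to each real window (normalized-target space)."""
        return self._np_score(wset.windows[wset.mask])

    def save(self, path):
        header = json.dumps(
            {"vocab_size": self.vocab_size, "embed_dim": self.embed_dim,
             "n_heads": self.n_heads, "pad_token": self.pad_token,
             "frozen": self.frozen}
        )
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "TinyEncoder":
        with np.load(path) as blob:
            header = json.loads(bytes(blob["__header__"]).decode())
            enc = cls(header["vocab_size"], header["embed_dim"], header["n_heads"],
                      header["pad_token"])
            enc.load_state_dict({k: blob[k] for k in blob.files if k != "__header__"})
            enc.frozen = header["frozen"]
        return enc


def median_baseline(encoder: TinyEncoder, wset: WindowSet) -> float:
    """Flat baseline: median of the independent window-level predictions.

    Even window counts take the mean of the two central order statistics.
    """
    return float(np.median(encoder.window_predictions(wset)))


def finetune_encoder(encoder, train_pairs, config, val_pairs=None) -> dict:
    """Fine-tune the encoder head-to-embeddings on window-level MSE.

    ``train_pairs`` is a list of ``(WindowSet, normalized target)``; every real
    window inherits its transcript's target. Early stopping follows validation
    MSE (train MSE when no validation pairs are supplied) with the configured
    patience, and the best checkpoint is restored.
    """
    if encoder.frozen:
        raise ValueError("cannot fine-tune a frozen encoder")
    if not train_pairs:
        raise ValueError("empty stage-1 training set")

    def flatten(pairs):
        xs = np.concatenate([ws.windows[ws.mask] for ws, _ in pairs], axis=0)
        ys = np.concatenate(
            [np.full(ws.n_windows, y, dtype=np.float64) for ws, y in pairs]
        )
        return xs, ys

    x_train, y_train = flatten(train_pairs)
    x_val, y_val = flatten(val_pairs) if val_pairs else (x_train, y_train)

    rng = np.random.default_rng(config.seed)
    opt = Adam(encoder.parameters(), lr=config.lr)
    history = {"train_mse": [], "val_mse": [], "best_epoch": -1, "epochs_run": 0}
    best_val, best_state, since_best = np.inf, encoder.state_dict(), 0
    n = len(x_train)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch):
            idx = order[start : start + config.batch]
            pred = encoder.forward_score(x_train[idx])
            loss = ((pred - y_train[idx]) ** 2.0).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        val_mse = float(np.mean((encoder._np_score(x_val) - y_val) ** 2))
        history["train_mse"].append(epoch_loss / n)
        history["val_mse"].append(val_mse)
        history["epochs_run"] = epoch + 1
        if val_mse < best_val - getattr(config, "min_delta", 0.0):
            best_val, best_state, since_best = val_mse, encoder.state_dict(), 0
            history["best_epoch"] = epoch
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    encoder.load_state_dict(best_state)
    return history
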