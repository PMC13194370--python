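"""Parameter containers and the small set of layers the models share."""

from __future__ import annotations

import hashlib

import numpy as np

from .autodiff import Tensor


class Module:
    """Lightweight parameter container with deterministic naming.

    Parameters are Tensors with ``requires_grad=True`` assigned as attributes
    (or inside lists of sub-Modules). Iteration order is sorted attribute
    name, so checksums and optimizer state are reproducible.
    """

    training: bool = True

    def named_parameters(self, prefix: str = ""):
        for name in sorted(vars(self)):
            obj = getattr(self, name)
            full = f"{prefix}{name}"
            if isinstance(obj, Tensor) and obj.requires_grad:
                yield full, obj
            elif isinstance(obj, Module):
                yield from obj.named_parameters(prefix=full + ".")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self._set_mode(True)

    def eval(self):
        self._set_mode(False)

    def _set_mode(self, flag: bool):
        self.training = flag
        for name in vars(self):
            obj = getattr(self, name)
            if isinstance(obj, Module):
                obj._set_mode(flag)
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    if isinstance(item, Module):
                        item._set_mode(flag)

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name, p in self.named_parameters():
            h.update(name.encode())
            h.update(p.data.tobytes())
        return h.hexdigest()


def uniform_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    """Dense layer; ``zero_init`` suits output heads on standardized targets
    (the untrained model then predicts the prior mean exactly)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            self.w = Tensor(np.zeros((d_in, d_out)), requires_grad=True)
            self.b = Tensor(np.zeros(d_out), requires_grad=True)
        else:
            self.w = uniform_init(rng, (d_in, d_out), d_in)
            self.b = uniform_init(rng, (d_out,), d_in)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc * (var + self.eps) ** (-0.5)) + self.beta


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * keep


class GRULayer(Module):
    """Single unidirectional GRU layer (reset/update/candidate gating)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.w_ih = uniform_init(rng, (d_in, 3 * hidden), hidden)
        self.w_hh = uniform_init(rng, (hidden, 3 * hidden), hidden)
        self.b_ih = uniform_init(rng, (3 * hidden,), hidden)
        self.b_hh = uniform_init(rng, (3 * hidden,), hidden)

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        H = self.hidden
        gx = x @ self.w_ih + self.b_ih
        gh = h @ self.w_hh + self.b_hh
        r = (gx[:, :H] + gh[:, :H]).sigmoid()
        z = (gx[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
        n = (gx[:, 2 * H :] + r * gh[:, 2 * H :]).tanh()
        return (1.0 - z) * n + z * h
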