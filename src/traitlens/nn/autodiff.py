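"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the traitlens models need: broadcasting
arithmetic, batched matmul, elementwise nonlinearities, reductions, fancy
indexing (for embedding lookup), reshape/transpose, stack/concat, and a
masked softmax. Everything runs in float64; gradients are accumulated by a
topological-order backward sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "stack", "concat", "masked_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_pairs")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._pairs = ()  # ((parent, grad_fn), ...)

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(data, pairs):
        pairs = tuple((p, f) for p, f in pairs if p.requires_grad)
        out = Tensor(data, requires_grad=bool(pairs))
        out._pairs = pairs
        return out

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data + o.data,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (o, lambda g: _unbroadcast(g, o.data.shape)),
            ],
        )

    __radd__ = __add__

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data * o.data,
            [
                (self, lambda g: _unbroadcast(g * o.data, self.data.shape)),
                (o, lambda g: _unbroadcast(g * self.data, o.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return (-self) + other

    def __truediv__(self, other):
        o = self._coerce(other)
        return self * o ** (-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p
        return Tensor._make(
            out_data,
            [(self, lambda g: g * p * self.data ** (p - 1.0))],
        )

    def __matmul__(self, other):
        o = self._coerce(other)
        if self.data.ndim < 2 or o.data.ndim < 2:
            raise ValueError("matmul requires operands with ndim >= 2")
        a, b = self.data, o.data
        return Tensor._make(
            a @ b,
            [
                (self, lambda g: _unbroadcast(g @ b.swapaxes(-1, -2), a.shape)),
                (o, lambda g: _unbroadcast(a.swapaxes(-1, -2) @ g, b.shape)),
            ],
        )

    # -- elementwise --------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, [(self, lambda g: g * out_data)])

    def log(self):
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, [(self, lambda g: g * (1.0 - out_data**2))])

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            out_data, [(self, lambda g: g * out_data * (1.0 - out_data))]
        )

    def relu(self):
        keep = self.data > 0
        return Tensor._make(self.data * keep, [(self, lambda g: g * keep)])

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor._make(out_data, [(self, back)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), [(self, lambda g: g.reshape(orig))]
        )

    def swapaxes(self, a, b):
        return Tensor._make(
            self.data.swapaxes(a, b), [(self, lambda g: g.swapaxes(a, b))]
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return full

        return Tensor._make(out_data, [(self, back)])

    # -- backward -----------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p, _ in node._pairs:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._pairs:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, fn in node._pairs:
                contrib = fn(g)
                key = id(p)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib


def stack(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.stack(datas, axis=axis)
    pairs = []
    for i, t in enumerate(tensors):
        pairs.append((t, lambda g, i=i: np.take(g, i, axis=axis)))
    return Tensor._make(out_data, pairs)


def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    pairs = []
    for i, t in enumerate(tensors):
        sl = [slice(None)] * out_data.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        pairs.append((t, lambda g, sl=tuple(sl): g[sl]))
    return Tensor._make(out_data, pairs)


def masked_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to `mask`-true entries.

    Masked-out entries come back exactly 0; rows must contain at least one
    true entry. Shift-invariant and overflow-safe: the shift is the row max
    over real entries, and masked logits never reach exp().
    """
    m = mask.astype(np.float64)
    if not np.all(m.sum(axis=-1) > 0):
        raise ValueError("masked_softmax: every row needs >=1 real entry")
    if not np.all(np.isfinite(logits.data[mask.astype(bool)])):
        raise ValueError("masked_softmax: nonfinite logits")
    shift = np.max(np.where(mask.astype(bool), logits.data, -np.inf), axis=-1, keepdims=True)
    e = ((logits - shift) * m).exp() * m
    return e / e.sum(axis=-1, keepdims=True)
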