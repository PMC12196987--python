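"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ndarray and remembers
how it was produced, so a single call to :meth:`Tensor.backward` accumulates
gradients into every upstream tensor created with ``requires_grad=True``.
The primitive set is deliberately small — elementwise arithmetic, matmul,
shape ops, reductions, a strided window gather for 1-D convolution — and
everything else (normalisation layers, softmax, attention, GELU) is composed
from it, which keeps each vector-Jacobian product trivially auditable.

Gradients of every primitive are verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _special

__all__ = ["Tensor", "as_tensor", "concatenate", "relu", "gelu", "erf", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp  # callable(grad_out) -> tuple of parent grads

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this node; accumulates into ``.grad`` of leaves."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._vjp is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(
            a.data + b.data,
            _parents=(a, b),
            _vjp=lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor(-a.data, _parents=(a,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(
            a.data * b.data,
            _parents=(a, b),
            _vjp=lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(
            a.data / b.data,
            _parents=(a, b),
            _vjp=lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data**2), b.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        return Tensor(
            a.data**p,
            _parents=(a,),
            _vjp=lambda g: (g * p * a.data ** (p - 1),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = np.matmul(a.data, b.data)

        def vjp(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            # collapse broadcast batch dims
            if ga.shape != a.data.shape:
                ga = _unbroadcast(ga, a.data.shape)
            if gb.shape != b.data.shape:
                gb = _unbroadcast(gb, b.data.shape)
            return ga, gb

        return Tensor(out, _parents=(a, b), _vjp=vjp)

    # ---------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor(
            a.data.reshape(shape),
            _parents=(a,),
            _vjp=lambda g: (g.reshape(old),),
        )

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)
        return Tensor(
            np.transpose(a.data, axes),
            _parents=(a,),
            _vjp=lambda g: (np.transpose(g, inv),),
        )

    def swapaxes(self, ax1, ax2):
        a = self
        return Tensor(
            np.swapaxes(a.data, ax1, ax2),
            _parents=(a,),
            _vjp=lambda g: (np.swapaxes(g, ax1, ax2),),
        )

    def __getitem__(self, idx):
        a = self
        out = a.data[idx]

        def vjp(g):
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            return (ga,)

        return Tensor(out, _parents=(a,), _vjp=vjp)

    def pad_last(self, before: int, after: int):
        """Zero-pad the last axis."""
        a = self
        width = [(0, 0)] * (a.data.ndim - 1) + [(before, after)]
        n = a.data.shape[-1]
        return Tensor(
            np.pad(a.data, width),
            _parents=(a,),
            _vjp=lambda g: (g[..., before : before + n],),
        )

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor(out, _parents=(a,), _vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            denom = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            denom = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    # ------------------------------------------------------------- elementwise
    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor(out, _parents=(a,), _vjp=lambda g: (g * out,))

    def log(self):
        a = self
        return Tensor(np.log(a.data), _parents=(a,), _vjp=lambda g: (g / a.data,))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return Tensor(out, _parents=(a,), _vjp=lambda g: (g * 0.5 / out,))

    def abs(self):
        a = self
        return Tensor(
            np.abs(a.data), _parents=(a,), _vjp=lambda g: (g * np.sign(a.data),)
        )

    def tanh(self):
        a = self
        out = np.tanh(a.data)
        return Tensor(out, _parents=(a,), _vjp=lambda g: (g * (1.0 - out**2),))

    # ----------------------------------------------------------- conv support
    def take_windows(self, kernel: int, stride: int = 1):
        """Gather sliding windows of the last axis.

        (..., L) -> (..., Lout, kernel) with Lout = (L - kernel)//stride + 1.
        Backward scatters window gradients back with ``kernel`` slice-adds.
        """
        a = self
        L = a.data.shape[-1]
        lout = (L - kernel) // stride + 1
        idx = stride * np.arange(lout)[:, None] + np.arange(kernel)[None, :]
        out = a.data[..., idx]

        def vjp(g):
            ga = np.zeros_like(a.data)
            for k in range(kernel):
                ga[..., k : k + stride * lout : stride] += g[..., :, k]
            return (ga,)

        return Tensor(out, _parents=(a,), _vjp=vjp)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        out = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            out.append(g[tuple(sl)])
        return tuple(out)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjp=vjp,
    )


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return Tensor(x.data * mask, _parents=(x,), _vjp=lambda g: (g * mask,))


def erf(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _special.erf(x.data)
    coef = 2.0 / np.sqrt(np.pi)
    return Tensor(
        out, _parents=(x,), _vjp=lambda g: (g * coef * np.exp(-x.data**2),)
    )


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    return x * (erf(x * (1.0 / np.sqrt(2.0))) + 1.0) * 0.5


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # constant max-shift for numerical stability; does not change the result
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)
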