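"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-free engine: each :class:`Tensor` wraps an ``ndarray`` and
remembers how it was produced, so calling :meth:`Tensor.backward` on a
scalar propagates gradients to every upstream tensor with
``requires_grad=True``.  The op set is exactly what the adversarial
graph-convolution models in this package need — broadcast arithmetic,
(batched) matmul, the usual activations, reductions, indexing, and a
gradient-reversal op whose forward pass is the identity while its backward
pass multiplies incoming gradients by ``-coeff``.

All computation is float64.  Graphs are rebuilt on every forward pass;
only :class:`~eegdann.nn.Parameter` objects persist between steps.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concatenate", "gradient_reversal"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that broadcasting introduced."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core -------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        # Gradients are only ever read or replaced (never mutated in place),
        # so aliasing views of other gradients here is safe.
        if self.grad is None:
            self.grad = np.asarray(g)
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Backpropagate from this scalar through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    # -- method forms --------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes=None):
        return transpose(self, axes)

    @property
    def T(self):
        return transpose(self)

    def detach(self) -> "Tensor":
        return Tensor(self.data)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
    return out


# ---------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data + b.data, (a, b))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))
        out._backward = _bw
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data * b.data, (a, b))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))
        out._backward = _bw
    return out


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _make(a.data / b.data, (a, b))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / b.data ** 2, b.data.shape))
        out._backward = _bw
    return out


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out = _make(a.data ** exponent, (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * exponent * a.data ** (exponent - 1.0))
        out._backward = _bw
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.ndim < 2 or b.ndim < 2:
        raise ValueError("matmul requires tensors with ndim >= 2")
    out = _make(np.matmul(a.data, b.data), (a, b))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))
        out._backward = _bw
    return out


# ---------------------------------------------------------------------
# elementwise nonlinearities
# ---------------------------------------------------------------------

def exp(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.exp(a.data), (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * out.data)
        out._backward = _bw
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    out = _make(np.log(a.data), (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad / a.data)
        out._backward = _bw
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    x = a.data
    with np.errstate(over="ignore"):
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out = _make(s, (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * out.data * (1.0 - out.data))
        out._backward = _bw
    return out


def leaky_relu(a, negative_slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    factor = np.where(a.data >= 0, 1.0, negative_slope)
    out = _make(a.data * factor, (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * factor)
        out._backward = _bw
    return out


def relu(a) -> Tensor:
    return leaky_relu(a, 0.0)


def maximum(a, scalar: float) -> Tensor:
    """Elementwise max against a constant; gradient is zero on the clamped side."""
    a = as_tensor(a)
    mask = (a.data >= scalar).astype(np.float64)
    out = _make(np.maximum(a.data, scalar), (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * mask)
        out._backward = _bw
    return out


def clip(a, lo: float, hi: float) -> Tensor:
    a = as_tensor(a)
    mask = ((a.data >= lo) & (a.data <= hi)).astype(np.float64)
    out = _make(np.clip(a.data, lo, hi), (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad * mask)
        out._backward = _bw
    return out


# ---------------------------------------------------------------------
# shape / reduction
# ---------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = _make(a.data.reshape(shape), (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(out.grad.reshape(a.data.shape))
        out._backward = _bw
    return out


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    out = _make(np.transpose(a.data, axes), (a,))
    if out.requires_grad:
        inv = None if axes is None else np.argsort(axes)
        def _bw():
            a._accumulate(np.transpose(out.grad, inv))
        out._backward = _bw
    return out


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = _make(a.data.sum(axis=axis, keepdims=keepdims), (a,))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        out._backward = _bw
    return out


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def concatenate(tensors: Iterable, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in ts], axis=axis), ts)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in ts]
        offsets = np.cumsum([0] + sizes)
        def _bw():
            for t, start, stop in zip(ts, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * out.grad.ndim
                    idx[axis] = slice(start, stop)
                    t._accumulate(out.grad[tuple(idx)])
        out._backward = _bw
    return out


def take(a, idx) -> Tensor:
    """General indexing; backward scatter-adds into the source positions."""
    a = as_tensor(a)
    out = _make(a.data[idx], (a,))
    if out.requires_grad:
        plain_slice = isinstance(idx, slice) or (
            isinstance(idx, tuple) and all(isinstance(i, (slice, int)) for i in idx))
        def _bw():
            g = np.zeros_like(a.data)
            if plain_slice:
                g[idx] += out.grad
            else:
                np.add.at(g, idx, out.grad)
            a._accumulate(g)
        out._backward = _bw
    return out


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))  # detached, for stability
    e = exp(a - shift)
    return div(e, tsum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------
# gradient reversal
# ---------------------------------------------------------------------

def gradient_reversal(a, coeff: float) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by ``-coeff``.

    For any downstream scalar loss, the gradient reaching ``a`` equals
    ``-coeff`` times the gradient that would reach it without this op.
    """
    a = as_tensor(a)
    if not np.isfinite(coeff):
        raise ValueError("gradient reversal coefficient must be finite")
    out = _make(a.data.copy(), (a,))
    if out.requires_grad:
        def _bw():
            a._accumulate(-coeff * out.grad)
        out._backward = _bw
    return out
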