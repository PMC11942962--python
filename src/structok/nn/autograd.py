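"""Minimal reverse-mode automatic differentiation over numpy arrays.

The models in this package are small (tens of thousands of parameters), so a
compact tape-based engine over float64 ndarrays is sufficient and keeps every
numerical path deterministic. The public surface mirrors the conventions of
the mainstream array-autograd libraries: a :class:`Tensor` wraps an ndarray,
operations build a graph, and ``backward()`` accumulates gradients into
``.grad`` of every tensor created with ``requires_grad=True``.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concatenate", "stack", "no_grad"]

_SQRT_2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )

        return Tensor._from_op(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out_data = self.data**p
        a = self

        def backward(g):
            return (g * p * a.data ** (p - 1.0),)

        return Tensor._from_op(out_data, (a,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = np.matmul(self.data, other.data)
        a, b = self, other

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

        return Tensor._from_op(out_data, (a, b), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        a = self

        def backward(g):
            return (g / a.data,)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            return (g * 0.5 / out_data,)

        return Tensor._from_op(out_data, (self,), backward)

    def abs(self):
        a = self

        def backward(g):
            return (g * np.sign(a.data),)

        return Tensor._from_op(np.abs(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data**2),)

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0)

        def backward(g):
            return (g * mask,)

        return Tensor._from_op(out_data, (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / _SQRT_2))
        out_data = x * phi

        def backward(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x**2)
            return (g * (phi + x * pdf),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        a = self

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a_norm(ax, a.data.ndim) for ax in axes):
                    g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor._from_op(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        out_data = self.data.reshape(shape)

        def backward(g):
            return (g.reshape(a.data.shape),)

        return Tensor._from_op(out_data, (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            return (np.swapaxes(g, ax1, ax2),)

        return Tensor._from_op(np.swapaxes(self.data, ax1, ax2), (a,), backward)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            return (np.transpose(g, inv),)

        return Tensor._from_op(np.transpose(self.data, axes), (a,), backward)

    def __getitem__(self, idx):
        a = self
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._from_op(out_data, (a,), backward)

    def take(self, indices, axis: int = 0):
        """Row lookup along ``axis`` with scatter-add gradient (embedding-style)."""
        indices = np.asarray(indices)
        a = self
        out_data = np.take(self.data, indices, axis=axis)

        def backward(g):
            full = np.zeros_like(a.data)
            if axis == 0:
                np.add.at(full, indices, g)
            else:  # pragma: no cover - only axis 0 used in models
                moved = np.moveaxis(full, axis, 0)
                np.add.at(moved, indices, np.moveaxis(g, axis, 0))
            return (full,)

        return Tensor._from_op(out_data, (a,), backward)

    def gather_last(self, indices: np.ndarray):
        """``out[..., i, j] = self[..., i, indices[i, j]]``.

        ``indices`` has shape (L, J) and is broadcast over the leading axes of
        ``self`` (shape ``(..., L, T)``). Used for relative-position score
        lookup in disentangled attention.
        """
        indices = np.asarray(indices)
        a = self
        idx = np.broadcast_to(
            indices, a.data.shape[:-1] + (indices.shape[-1],)
        )
        out_data = np.take_along_axis(a.data, idx, axis=-1)

        def backward(g):
            full = np.zeros_like(a.data)
            flat = full.reshape(-1, full.shape[-1])
            gflat = g.reshape(-1, g.shape[-1])
            iflat = idx.reshape(-1, idx.shape[-1])
            rows = np.repeat(np.arange(flat.shape[0]), iflat.shape[-1])
            np.add.at(flat, (rows, iflat.ravel()), gflat.ravel())
            return (full,)

        return Tensor._from_op(out_data, (a,), backward)

    # -- composite numerics ---------------------------------------------------
    def softmax(self, axis: int = -1):
        # subtracting the (detached) max is the usual overflow guard and does
        # not change the derivative
        shifted = self + Tensor(-self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def norm(self, axis: int = -1, keepdims: bool = False, eps: float = 1e-8):
        """Euclidean norm along ``axis``, smoothed at zero for differentiability."""
        return ((self**2.0).sum(axis=axis, keepdims=keepdims) + eps).sqrt()

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate into .grad
                if node.grad is None:
                    node.grad = np.zeros_like(node.data)
                node.grad = node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._prev, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def a_norm(ax: int, ndim: int) -> int:
    return ax % ndim


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._from_op(out_data, tuple(tensors), backward)
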