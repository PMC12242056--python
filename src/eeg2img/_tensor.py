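"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the EEG encoder and the embedding-space
diffusion prior need: broadcasting arithmetic, matmul, reshape/transpose/
slicing/concatenation, reductions, exp/log/tanh/erf, and a 1-D ``unfold``
primitive from which the convolutions are built.  Everything is float64.

Gradients are accumulated by topological sort over the tape recorded during
the forward pass; ``no_grad`` disables taping for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from scipy import special as _sp

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling gradient taping."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        parents = tuple(p for p in parents if p.requires_grad)
        out = Tensor(data, requires_grad=bool(parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __pow__(self, exponent: float):
        return self.pow(exponent)

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (self,), backward)

    def erf(self) -> "Tensor":
        def backward(g):
            self._accum(g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data ** 2))

        return Tensor._make(_sp.erf(self.data), (self,), backward)

    def clip(self, lo: float | None, hi: float | None) -> "Tensor":
        """Clamp values; gradient passes only through the unclipped region."""
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask = mask * (self.data >= lo)
        if hi is not None:
            mask = mask * (self.data <= hi)

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), backward)

    # -- linear algebra -------------------------------------------------------
    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.shape

        def backward(g):
            self._accum(g.reshape(in_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.transpose(g, inv))

        return Tensor._make(np.transpose(self.data, axes), (self,), backward)

    def __getitem__(self, idx) -> "Tensor":
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.shape

        ndim = self.ndim

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, in_shape).copy())
                return
            axes = tuple(a % ndim for a in
                         (axis if isinstance(axis, tuple) else (axis,)))
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, in_shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.shape[a % self.ndim] for a in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# -- free functions -----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(out_data, tensors, backward)


def unfold_last(x: Tensor, kernel: int, pad: int = 0) -> Tensor:
    """Sliding windows over the last axis.

    Input ``(..., L)`` -> output ``(..., L_out, kernel)`` with
    ``L_out = L + 2*pad - kernel + 1``.
    """
    x = Tensor._coerce(x)
    L = x.shape[-1]
    data = x.data
    if pad:
        width = [(0, 0)] * (data.ndim - 1) + [(pad, pad)]
        data = np.pad(data, width)
    windows = np.lib.stride_tricks.sliding_window_view(data, kernel, axis=-1)
    out_data = np.ascontiguousarray(windows)
    L_out = out_data.shape[-2]

    def backward(g):
        padded = np.zeros(x.shape[:-1] + (L + 2 * pad,))
        for i in range(kernel):
            padded[..., i:i + L_out] += g[..., :, i]
        x._accum(padded[..., pad:pad + L] if pad else padded)

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit, exact erf form."""
    return x * 0.5 * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0)
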