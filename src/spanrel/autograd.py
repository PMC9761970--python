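"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the extraction model needs are implemented: affine maps,
attention arithmetic (matmul / softmax pieces), elementwise nonlinearities,
reductions, concatenation and row gathering for embeddings.  Everything is
dense float64 and single-threaded; the model dimensions this package uses
(d = 64, sentences of a few dozen tokens) keep graphs small enough that a
plain Python tape is not a bottleneck.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and is_grad_enabled()
        self._backward = None
        self._prev = _prev if self.requires_grad else ()
        self.name = name

    # -- graph plumbing -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(
            fwd(self.data, other.data),
            requires_grad=self.requires_grad or other.requires_grad,
            _prev=(self, other),
        )
        if out.requires_grad:
            def _backward():
                g = out.grad
                if self.requires_grad:
                    self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))
            out._backward = _backward
        return out

    def _unary(self, fwd, bwd) -> "Tensor":
        out = Tensor(fwd(self.data), requires_grad=self.requires_grad, _prev=(self,))
        if out.requires_grad:
            def _backward():
                self._accum(bwd(out.grad, self.data, out.data))
            out._backward = _backward
        return out

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return self._unary(lambda a: -a, lambda g, a, o: -g)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _prev=(self, other))
        if out.requires_grad:
            def _backward():
                # promote 1-D operands so the transpose algebra is uniform
                a = self.data if self.data.ndim > 1 else self.data[None, :]
                b = other.data if other.data.ndim > 1 else other.data[:, None]
                g = out.grad
                if self.data.ndim == 1:
                    g = g[None, ...]
                if other.data.ndim == 1:
                    g = g[..., None]
                if self.requires_grad:
                    da = g @ np.swapaxes(b, -1, -2)
                    if self.data.ndim == 1:
                        da = da[..., 0, :]       # drop the promoted row axis
                    self._accum(_unbroadcast(da, self.data.shape))
                if other.requires_grad:
                    db = np.swapaxes(a, -1, -2) @ g
                    if other.data.ndim == 1:
                        db = db[..., 0]          # drop the promoted column axis
                    other._accum(_unbroadcast(db, other.data.shape))
            out._backward = _backward
        return out

    # -- elementwise --------------------------------------------------------

    def exp(self):
        return self._unary(np.exp, lambda g, a, o: g * o)

    def log(self):
        return self._unary(np.log, lambda g, a, o: g / a)

    def sqrt(self):
        return self._unary(np.sqrt, lambda g, a, o: g / (2.0 * o))

    def tanh(self):
        return self._unary(np.tanh, lambda g, a, o: g * (1.0 - o * o))

    def relu(self):
        return self._unary(lambda a: np.maximum(a, 0.0),
                           lambda g, a, o: g * (a > 0.0))

    def sigmoid(self):
        return self._unary(lambda a: 1.0 / (1.0 + np.exp(-a)),
                           lambda g, a, o: g * o * (1.0 - o))

    # -- reductions / shape -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _prev=(self,))
        if out.requires_grad:
            def _backward():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape),
                     requires_grad=self.requires_grad, _prev=(self,))
        if out.requires_grad:
            def _backward():
                self._accum(out.grad.reshape(self.data.shape))
            out._backward = _backward
        return out

    def transpose(self, ax0: int = -2, ax1: int = -1):
        out = Tensor(np.swapaxes(self.data, ax0, ax1),
                     requires_grad=self.requires_grad, _prev=(self,))
        if out.requires_grad:
            def _backward():
                self._accum(np.swapaxes(out.grad, ax0, ax1))
            out._backward = _backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, _prev=(self,))
        if out.requires_grad:
            def _backward():
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)
            out._backward = _backward
        return out

    # -- softmax family (numerically stable, built on the tape) -------------

    def softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        shifted = self - self.data.max(axis=axis, keepdims=True)
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _prev=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _backward():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis if axis >= 0 else out.grad.ndim + axis] = slice(lo, hi)
                    t._accum(out.grad[tuple(sl)])
        out._backward = _backward
    return out


def gather_rows(table: Tensor, indices: np.ndarray) -> Tensor:
    """Embedding lookup: rows of `table` at integer `indices` (scatter-add grad)."""
    indices = np.asarray(indices, dtype=np.intp)
    out = Tensor(table.data[indices], requires_grad=table.requires_grad, _prev=(table,))
    if out.requires_grad:
        def _backward():
            g = np.zeros_like(table.data)
            np.add.at(g, indices, out.grad)
            table._accum(g)
        out._backward = _backward
    return out
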