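"""Minimal reverse-mode automatic differentiation on numpy arrays.

The embedding network is affine and the training objective is a sum of
closed-form penalty terms (standard deviations, covariances, pairwise
distances, softmax cross terms), so a small tensor engine covering the
arithmetic ops those terms use is sufficient.  Gradients are accumulated
by topological-order backpropagation; broadcasting is supported in the
elementwise ops by summing gradients over broadcast axes.

Only the operations the loss terms actually use are implemented.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "gather_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after a broadcast forward op."""
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
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # numpy defers binary ops to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------
    # construction helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    # graph plumbing
    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------------
    # arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def bwd(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd, rg)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd, self.requires_grad)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd, rg)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), bwd, rg)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd, self.requires_grad)

    def __matmul__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bwd, rg)

    # ------------------------------------------------------------------
    # elementwise functions
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd, self.requires_grad)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd, self.requires_grad)

    def abs(self):
        def bwd(g):
            self._accum(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bwd, self.requires_grad)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-300))

        return Tensor._make(out_data, (self,), bwd, self.requires_grad)

    # ------------------------------------------------------------------
    # reductions & shaping
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), bwd, self.requires_grad)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def std(self, axis=None, eps: float = 1e-18):
        """Population standard deviation (ddof=0), smoothed at zero.

        ``eps`` inside the square root keeps the gradient finite for
        constant slices; it perturbs the value by at most sqrt(eps).
        """
        mu = self.mean(axis=axis, keepdims=True)
        var = ((self - mu) ** 2).mean(axis=axis)
        return (var + eps).sqrt()

    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape
        old = self.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bwd, self.requires_grad)

    @property
    def T(self):
        def bwd(g):
            self._accum(g.T)

        return Tensor._make(self.data.T, (self,), bwd, self.requires_grad)

    def take_rows(self, idx):
        """Select rows (axis 0) by integer index; repeated rows allowed."""
        idx = np.asarray(idx, dtype=np.intp)

        def bwd(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        return Tensor._make(self.data[idx], (self,), bwd, self.requires_grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate along ``axis`` with gradient routed back per block."""
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    rg = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), bwd, rg)


def gather_rows(t: Tensor, cols) -> Tensor:
    """``t[i, cols[i]]`` for a 2-D tensor — one element per row."""
    t = as_tensor(t)
    cols = np.asarray(cols, dtype=np.intp)
    rows = np.arange(t.shape[0])

    def bwd(g):
        acc = np.zeros_like(t.data)
        np.add.at(acc, (rows, cols), g)
        t._accum(acc)

    return Tensor._make(t.data[rows, cols], (t,), bwd, t.requires_grad)
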