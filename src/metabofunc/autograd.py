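"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains small graph neural networks and multilayer perceptrons on
CPU; this module supplies the tensor/backprop machinery they need and nothing
more.  Tensors wrap ``numpy.ndarray`` values and record the operations applied
to them; calling :meth:`Tensor.backward` on a scalar loss accumulates
gradients into every upstream tensor created with ``requires_grad=True``.

Supported primitives: elementwise arithmetic with broadcasting, matmul,
exp/log, relu/leaky_relu/sigmoid, sum/mean, reshape/concat/slicing, row
gather, and segment (scatter-add) sums -- the last two are what message
passing and graph readout are built from.  Gradients are checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
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
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ misc
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(out):
            if self.requires_grad:
                self._accumulate(-out.grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        return self._make(self.data @ other.data, (self, other), backward)

    # ---------------------------------------------------------- nonlinearity
    def exp(self):
        val = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * val)

        return self._make(val, (self,), backward)

    def log(self):
        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        return self._make(self.data * mask, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * factor)

        return self._make(self.data * factor, (self,), backward)

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad * val * (1.0 - val))

        return self._make(val, (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        def backward(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        def backward(out):
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, key):
        def backward(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accumulate(g)

        return self._make(self.data[key], (self,), backward)

    # --------------------------------------------------------------- autodiff
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep for many epochs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)
            # free graph references as we go
            node._backward = None
            node._prev = ()


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def backward(o):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * o.grad.ndim
                    idx[axis] = slice(lo, hi)
                    t._accumulate(o.grad[tuple(idx)])

        out._prev = tuple(tensors)
        out._backward = backward
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]`` (first axis); backward scatter-adds."""
    index = np.asarray(index, dtype=np.int64)

    def backward(out):
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, index, out.grad)
            x._accumulate(g)

    return x._make(x.data[index], (x,), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given by ``segment_ids``.

    The workhorse of message aggregation (bucket = destination node) and of
    sum-pooling graph readout (bucket = molecule index in the batch).
    """
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, segment_ids, x.data)

    def backward(out):
        if x.requires_grad:
            x._accumulate(out.grad[segment_ids])

    return x._make(out_data, (x,), backward)
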