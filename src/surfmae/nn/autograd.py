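"""Minimal reverse-mode automatic differentiation over numpy arrays.

The networks in this package are small (a few dozen tokens, widths of a few
hundred), so a compact tape-based autograd with float64 numerics is both fast
enough and easy to verify against finite differences. Only the primitives the
models actually use are implemented: broadcast arithmetic, matmul, reductions
(sum / mean / max / min), exp/log/tanh/erf-free GELU, softmax, reshape /
transpose / concatenate, and integer-array gather.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _make(data, parents, backward, requires_grad):
        out = Tensor(data)
        if requires_grad:
            out.requires_grad = True
            out._parents = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), backward, req)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), backward, req)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(self.data / other.data, (self, other), backward, req)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), backward, self.requires_grad)

    def __matmul__(self, other):
        other = as_tensor(other)
        req = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward, req)

    # -------------------------------------------------------------- unary ops
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward, self.requires_grad)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward, self.requires_grad)

    def gelu(self):
        # tanh-form GELU; exact gradient of this closed form
        c = np.sqrt(2.0 / np.pi)
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
            self._accum(g * d)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward, self.requires_grad
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first argmax (tie-break)."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    def min(self, axis: int, keepdims: bool = False):
        return -((-self).max(axis=axis, keepdims=keepdims))

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward, self.requires_grad)

    # ------------------------------------------------------------ shape / view
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward, self.requires_grad)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward, self.requires_grad)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward, self.requires_grad)

    def broadcast_to(self, shape):
        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))

        return Tensor._make(
            np.broadcast_to(self.data, shape).copy(), (self,), backward, self.requires_grad
        )


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward, req
    )


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)

    def backward(g):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accum(gp)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, backward, req)
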