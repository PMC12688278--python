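"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the model needs: broadcasting arithmetic,
matrix products, row gathering, reductions, the usual nonlinearities and a
clip with straight-through-zero gradient outside the interval.  Everything
is float64; graphs are built eagerly and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat_cols", "softmax_rows", "stack1d", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        a, b = self.data, other.data

        def bw(g):
            g = np.atleast_2d(g)
            ga = g @ np.atleast_2d(b).T if b.ndim > 1 else np.outer(g, b)
            gb = np.atleast_2d(a).T @ g if a.ndim > 1 else np.outer(a, g)
            return (
                ga.reshape(a.shape) if ga.size == a.size else _unbroadcast(ga, a.shape),
                gb.reshape(b.shape) if gb.size == b.size else _unbroadcast(gb, b.shape),
            )

        out._backward = bw
        return out

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- shape ops -----------------------------------------------------------
    @property
    def T(self):
        out = Tensor(self.data.T, _parents=(self,))
        out._backward = lambda g: (g.T,)
        return out

    def take_rows(self, idx):
        """Gather rows (scatter-add on backward)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], _parents=(self,))
        shape = self.data.shape

        def bw(g):
            full = np.zeros(shape)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bw
        return out

    def reshape(self, *shape):
        old = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: (g.reshape(old),)
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        shape = self.data.shape

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(out_data, _parents=(self,))
        shape = self.data.shape

        def bw(g):
            gg = g
            od = out_data
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
                od = np.expand_dims(out_data, axis)
            mask = (self.data == od).astype(np.float64)
            mask /= mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            return (_unbroadcast(gg * mask, shape) if gg.shape != shape else gg * mask,)

        out._backward = bw
        return out

    # -- elementwise nonlinear ----------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: (g * out.data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def leaky_relu(self, slope: float = 0.01):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _parents=(self,))
        out._backward = lambda g: (g * np.where(self.data > 0, 1.0, slope),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero outside [lo, hi] (hard clip)."""
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))
        inside = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda g: (g * inside,)
        return out

    # -- backward ------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: loss graphs can be deeper than the recursion limit
            t, processed = stack.pop()
            if processed:
                order.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        for t in order:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if p.requires_grad and g is not None:
                    p.grad = p.grad + g if p.grad is not None else g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    """Column-wise concatenation of two 2-D tensors."""
    a, b = as_tensor(a), as_tensor(b)
    na = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), _parents=(a, b))
    out._backward = lambda g: (g[:, :na], g[:, na:])
    return out


def stack1d(tensors) -> Tensor:
    """Concatenate scalar/1-D tensors into one 1-D tensor."""
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.data.size for t in ts]
    out = Tensor(np.concatenate([t.data.ravel() for t in ts]), _parents=tuple(ts))

    def bw(g):
        grads, off = [], 0
        for t, s in zip(ts, sizes):
            grads.append(g[off:off + s].reshape(t.data.shape))
            off += s
        return tuple(grads)

    out._backward = bw
    return out


def softmax_rows(z: Tensor) -> Tensor:
    """Numerically stable row-wise softmax built from primitives."""
    z = as_tensor(z)
    if z.ndim == 1:
        shifted = z - Tensor(z.data.max())
        e = shifted.exp()
        return e / e.sum()
    shifted = z - Tensor(z.data.max(axis=1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
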