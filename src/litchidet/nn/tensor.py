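"""Minimal reverse-mode autodiff on numpy arrays.

The detector graphs need a small, fixed vocabulary of differentiable
operations (convolution, pooling, normalisation, pointwise arithmetic,
reshapes and gathers).  A tape of ``Tensor`` nodes records the forward
pass; ``Tensor.backward`` walks it in reverse topological order.  All
data is float32; gradients accumulate in float32 as well.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """Array node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def detach(self):
        return Tensor(self.data)

    def numpy(self):
        return self.data

    def zero_grad(self):
        self.grad = None

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                pgrad = _unbroadcast(pgrad, parent.data.shape)
                if parent.grad is None:
                    parent.grad = pgrad.astype(np.float32, copy=True)
                else:
                    parent.grad += pgrad

    # -- pointwise arithmetic ------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return Tensor(self.data + other.data, parents=(self, other),
                      backward=lambda g: [(self, g), (other, g)])

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor(self.data - other.data, parents=(self, other),
                      backward=lambda g: [(self, g), (other, -g)])

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor(self.data * other.data, parents=(self, other),
                      backward=lambda g: [(self, g * other.data), (other, g * self.data)])

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor(self.data / other.data, parents=(self, other),
                      backward=lambda g: [(self, g / other.data),
                                          (other, -g * self.data / other.data ** 2)])

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return Tensor(-self.data, parents=(self,), backward=lambda g: [(self, -g)])

    def __pow__(self, p):
        p = float(p)
        return Tensor(self.data ** p, parents=(self,),
                      backward=lambda g: [(self, g * p * self.data ** (p - 1))])

    # -- pointwise functions -------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(s, parents=(self,), backward=lambda g: [(self, g * s * (1 - s))])

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(self.data * s, parents=(self,),
                      backward=lambda g: [(self, g * s * (1 + self.data * (1 - s)))])

    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=(self,), backward=lambda g: [(self, g * mask)])

    def exp(self):
        e = np.exp(self.data)
        return Tensor(e, parents=(self,), backward=lambda g: [(self, g * e)])

    def log(self):
        return Tensor(np.log(self.data), parents=(self,),
                      backward=lambda g: [(self, g / self.data)])

    def sqrt(self):
        r = np.sqrt(self.data)
        return Tensor(r, parents=(self,), backward=lambda g: [(self, g * 0.5 / np.maximum(r, 1e-12))])

    def arctan(self):
        return Tensor(np.arctan(self.data), parents=(self,),
                      backward=lambda g: [(self, g / (1 + self.data ** 2))])

    def clamp(self, lo=None, hi=None):
        out = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask *= self.data >= lo
        if hi is not None:
            mask *= self.data <= hi
        return Tensor(out, parents=(self,), backward=lambda g: [(self, g * mask)])

    def minimum(self, other):
        other = as_tensor(other)
        mask = self.data <= other.data
        return Tensor(np.minimum(self.data, other.data), parents=(self, other),
                      backward=lambda g: [(self, g * mask), (other, g * ~mask)])

    def maximum(self, other):
        other = as_tensor(other)
        mask = self.data >= other.data
        return Tensor(np.maximum(self.data, other.data), parents=(self, other),
                      backward=lambda g: [(self, g * mask), (other, g * ~mask)])

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return [(self, np.broadcast_to(gg, self.data.shape))]

        return Tensor(out, parents=(self,), backward=back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_spatial(self):
        """Global max over the trailing H, W axes of an NCHW tensor."""
        n, c, h, w = self.data.shape
        flat = self.data.reshape(n, c, h * w)
        idx = flat.argmax(axis=2)
        out = np.take_along_axis(flat, idx[..., None], axis=2)[..., 0]

        def back(g):
            gx = np.zeros_like(flat)
            np.put_along_axis(gx, idx[..., None], g[..., None], axis=2)
            return [(self, gx.reshape(self.data.shape))]

        return Tensor(out, parents=(self,), backward=back)

    def max_channel(self, keepdims=True):
        """Max over the channel axis of an NCHW tensor."""
        idx = self.data.argmax(axis=1)
        out = np.take_along_axis(self.data, idx[:, None], axis=1)
        if not keepdims:
            out = out[:, 0]

        def back(g):
            gg = g if keepdims and g.ndim == self.data.ndim else g[:, None]
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, idx[:, None], gg, axis=1)
            return [(self, gx)]

        return Tensor(out, parents=(self,), backward=back)

    # -- shape manipulation --------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(self.data.reshape(shape), parents=(self,),
                      backward=lambda g: [(self, g.reshape(old))])

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor(self.data.transpose(axes), parents=(self,),
                      backward=lambda g: [(self, g.transpose(inv))])

    def __getitem__(self, key):
        out = self.data[key]

        def back(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            return [(self, gx)]

        return Tensor(out, parents=(self,), backward=back)

    def matmul(self, other):
        other = as_tensor(other)
        out = self.data @ other.data
        return Tensor(out, parents=(self, other),
                      backward=lambda g: [(self, g @ other.data.swapaxes(-1, -2)),
                                          (other, self.data.swapaxes(-1, -2) @ g)])

    @staticmethod
    def concat(tensors, axis=1):
        datas = [t.data for t in tensors]
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def back(g):
            return list(zip(tensors, np.split(g, splits, axis=axis)))

        return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=back)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum-reduce a broadcast gradient back to ``shape``."""
    grad = np.asarray(grad, dtype=np.float32)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad
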