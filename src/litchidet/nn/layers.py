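"""Neural-network layers on top of the autodiff tape.

Convolutions are evaluated by the im2col route: a strided
sliding-window view feeds a single tensordot/einsum per layer, which is
where numpy spends its time in large matrix products.  Only the two
group settings the detector family uses are implemented: dense
(``groups=1``) and depthwise (``groups=channels``).
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "Module", "Parameter", "Conv2d", "BatchNorm2d", "SiLU", "ReLU", "Sigmoid",
    "Identity", "MaxPool2d", "UpsampleNearest2x", "Sequential",
]


def _flatten(seq):
    for item in seq:
        if isinstance(item, (list, tuple)):
            yield from _flatten(item)
        else:
            yield item


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter/submodule discovery."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            path = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(path)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(_flatten(value)):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in _flatten(value):
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                out[f"__bn{i}.running_mean"] = m.running_mean.copy()
                out[f"__bn{i}.running_var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = state[f"__bn{i}.running_mean"]
                m.running_var[...] = state[f"__bn{i}.running_var"]


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, groups=1,
                 bias=False, rng=None):
        super().__init__()
        if groups not in (1, in_ch):
            raise ValueError("only dense (groups=1) or depthwise (groups=in_ch) supported")
        if groups == in_ch and out_ch != in_ch:
            raise ValueError("depthwise convolution requires out_ch == in_ch")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding, self.groups = kernel, stride, padding, groups
        fan_in = in_ch // groups * kernel * kernel
        bound = 1.0 / math.sqrt(fan_in)
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.uniform(-bound, bound,
                                            (out_ch, in_ch // groups, kernel, kernel)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.padding
        data = x.data
        if p:
            data = np.pad(data, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(data, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # win: (N, C, Ho, Wo, k, k)
        w = self.weight.data
        if self.groups == 1:
            out = np.tensordot(win, w, axes=((1, 4, 5), (1, 2, 3)))  # (N,Ho,Wo,O)
            out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        else:
            out = np.einsum("nchwij,cij->nchw", win, w[:, 0], optimize=True)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None]
        parents = (x, self.weight) + ((self.bias,) if self.bias is not None else ())

        def back(g):
            grads = []
            if self.groups == 1:
                gw = np.tensordot(g, win, axes=((0, 2, 3), (0, 2, 3)))  # (O,C,k,k)
                gcol = np.tensordot(g, w, axes=((1,), (0,)))  # (N,Ho,Wo,C,k,k)
                gcol = gcol.transpose(0, 3, 1, 2, 4, 5)
            else:
                gw = np.einsum("nchw,nchwij->cij", g, win, optimize=True)[:, None]
                gcol = np.einsum("nchw,cij->nchwij", g, w[:, 0], optimize=True)
            n, _, hi, wi = x.data.shape
            gx = np.zeros((n, self.in_ch, hi + 2 * p, wi + 2 * p), dtype=np.float32)
            ho, wo = g.shape[2], g.shape[3]
            for i in range(k):
                for j in range(k):
                    gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcol[..., i, j]
            if p:
                gx = gx[:, :, p:-p, p:-p]
            grads.append((x, gx))
            grads.append((self.weight, gw))
            if self.bias is not None:
                grads.append((self.bias, g.sum(axis=(0, 2, 3))))
            return grads

        return Tensor(out, parents=parents, backward=back)


class BatchNorm2d(Module):
    def __init__(self, ch, eps=1e-3, momentum=0.03):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            n = x.data.size / self.ch
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * n / max(n - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
        out = xhat * self.weight.data[None, :, None, None] + self.bias.data[None, :, None, None]
        training = self.training

        def back(g):
            gw = (g * xhat).sum(axis=(0, 2, 3))
            gb = g.sum(axis=(0, 2, 3))
            gxhat = g * self.weight.data[None, :, None, None]
            if training:
                n = x.data.size / self.ch
                gx = (gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
                      - xhat * (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True))
                gx = gx * inv[None, :, None, None]
                del n
            else:
                gx = gxhat * inv[None, :, None, None]
            return [(x, gx), (self.weight, gw), (self.bias, gb)]

        return Tensor(out, parents=(x, self.weight, self.bias), backward=back)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel, stride, padding=0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.kernel, self.stride, self.padding
        data = x.data
        if p:
            data = np.pad(data, ((0, 0), (0, 0), (p, p), (p, p)),
                          constant_values=-np.inf)
        win = sliding_window_view(data, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, ho, wo = win.shape[:4]
        flat = win.reshape(n, c, ho, wo, k * k)
        idx = flat.argmax(axis=4)
        out = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]
        hp, wp = data.shape[2], data.shape[3]

        def back(g):
            gx = np.zeros((n, c, hp, wp), dtype=np.float32)
            ii, jj = np.divmod(idx, k)
            rows = (np.arange(ho)[None, None, :, None] * s + ii)
            cols = (np.arange(wo)[None, None, None, :] * s + jj)
            nn = np.arange(n)[:, None, None, None]
            cc = np.arange(c)[None, :, None, None]
            np.add.at(gx, (nn, cc, rows, cols), g)
            if p:
                gx = gx[:, :, p:-p, p:-p]
            return [(x, gx)]

        return Tensor(out, parents=(x,), backward=back)


class UpsampleNearest2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        out = x.data.repeat(2, axis=2).repeat(2, axis=3)
        n, c, h, w = x.data.shape

        def back(g):
            return [(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))]

        return Tensor(out, parents=(x,), backward=back)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x
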