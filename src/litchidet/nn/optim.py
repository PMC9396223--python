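"""Optimisers for the numpy network stack."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW"]


class AdamW:
    """AdamW with decoupled weight decay.

    ``beta1`` doubles as the "momentum" slot of the training
    configuration; decay is not applied to parameters flagged in
    ``no_decay`` (batch-norm affine terms and biases, by convention).
    """

    def __init__(self, params, lr=0.01, beta1=0.937, beta2=0.999, eps=1e-8,
                 weight_decay=5e-3, no_decay=()):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.no_decay = set(id(p) for p in no_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.weight_decay and id(p) not in self.no_decay:
                p.data *= 1 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
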