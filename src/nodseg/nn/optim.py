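"""First-order optimizers: Adam, AdamW (decoupled weight decay) and RAdam."""

from __future__ import annotations

import math

import numpy as np


class _AdamBase:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            self._update(i, p, p.grad)

    def _update(self, i, p, g):
        raise NotImplementedError


class Adam(_AdamBase):
    """Adam with L2 regularization folded into the gradient."""

    def _update(self, i, p, g):
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
        mhat = self.m[i] / (1 - self.b1 ** self.t)
        vhat = self.v[i] / (1 - self.b2 ** self.t)
        p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AdamW(_AdamBase):
    """Adam with decoupled weight decay applied directly to the weights."""

    def _update(self, i, p, g):
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
        mhat = self.m[i] / (1 - self.b1 ** self.t)
        vhat = self.v[i] / (1 - self.b2 ** self.t)
        p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                             + self.weight_decay * p.data)


class RAdam(_AdamBase):
    """Rectified Adam: variance-rectified adaptive step, SGD-with-momentum
    fallback while the rectification term is undefined (early steps)."""

    def _update(self, i, p, g):
        if self.weight_decay:
            g = g + self.weight_decay * p.data
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
        mhat = self.m[i] / (1 - self.b1 ** self.t)
        rho_inf = 2.0 / (1 - self.b2) - 1.0
        b2t = self.b2 ** self.t
        rho = rho_inf - 2.0 * self.t * b2t / (1 - b2t)
        if rho > 4.0:
            vhat = np.sqrt(self.v[i] / (1 - b2t))
            r = math.sqrt(((rho - 4) * (rho - 2) * rho_inf)
                          / ((rho_inf - 4) * (rho_inf - 2) * rho))
            p.data -= self.lr * r * mhat / (vhat + self.eps)
        else:
            p.data -= self.lr * mhat


OPTIMIZERS = {"Adam": Adam, "AdamW": AdamW, "RAdam": RAdam}


def make_optimizer(name: str, params, lr: float, weight_decay: float = 0.0):
    try:
        cls = OPTIMIZERS[name]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    return cls(params, lr=lr, weight_decay=weight_decay)
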