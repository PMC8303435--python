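"""Rectified Adam (RAdam).

Adam's adaptive step has pathologically large variance early in training when
the second-moment estimate rests on few samples.  RAdam computes the length
rho_t of the approximated SMA; while rho_t <= 4 the variance is intractable
and the update falls back to (bias-corrected) momentum SGD, afterwards the
adaptive step is used with the analytic rectification factor r_t.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .tensor import Tensor


class RAdam:
    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.b1, self.b2
        b2t = b2 ** t
        rho_t = self.rho_inf - 2.0 * t * b2t / (1.0 - b2t)
        if rho_t > 4.0:
            r = np.sqrt(((rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf)
                        / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t))
        else:
            r = None
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            mhat = m / (1.0 - b1 ** t)
            if r is not None:
                vhat = np.sqrt(v / (1.0 - b2t)) + self.eps
                p.data -= (self.lr * r) * mhat / vhat
            else:
                p.data -= self.lr * mhat

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
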