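"""Adam optimizer for the functional-gradient API."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, grad

__all__ = ["Adam"]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.0, 0.99), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, loss: Tensor, lr_scale: float = 1.0) -> None:
        """One update from the gradients of ``loss`` w.r.t. the tracked params."""
        gs = grad(loss, self.params)
        self.t += 1
        for p, g, m, v in zip(self.params, gs, self.m, self.v):
            gd = g.data
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= lr_scale * self.lr * mhat / (np.sqrt(vhat) + self.eps)
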