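"""AdamW: Adam with decoupled weight decay."""

from __future__ import annotations

import numpy as np

from viewseg.nn.layers import Param


class AdamW:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 weight_decay: float = 0.0, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            if self.wd and p.decay:
                p.value -= self.lr * self.wd * p.value
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
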