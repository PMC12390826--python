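"""Stochastic gradient descent with classical momentum and weight decay."""

from __future__ import annotations

import numpy as np

from .layers import Module


class SGD:
    """v <- mu*v + (grad + wd*w); w <- w - lr*v (decoupled from batch size)."""

    def __init__(self, model: Module, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        if lr < 0 or momentum < 0 or weight_decay < 0:
            raise ValueError("lr, momentum and weight_decay must be >= 0")
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in model.parameters()]

    def zero_grad(self) -> None:
        self.model.zero_grad()

    def step(self) -> None:
        for v, p in zip(self._velocity, self.model.parameters()):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
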