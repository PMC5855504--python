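"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

from .layers import Param


class SGD:
    """v ← μ·v − lr·g;  p ← p + v.  Gradients are zeroed by the caller."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        if not 0.0 <= momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
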