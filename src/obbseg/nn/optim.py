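"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class SGD:
    """SGD with momentum and decoupled-from-loss L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** self._t)
            vh = v / (1 - b2 ** self._t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def poly_decay(base_lr: float, it: int, max_it: int, power: float = 0.9,
               min_lr: float = 0.0) -> float:
    """Polynomial learning-rate decay: lr = base * (1 - it/max_it)^power."""
    frac = min(max(it / max(max_it, 1), 0.0), 1.0)
    return max(base_lr * (1.0 - frac) ** power, min_lr)
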