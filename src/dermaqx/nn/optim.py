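"""AdamW and the cosine-annealing-with-warm-restarts learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

from .layers import Parameter


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay multiplies the parameter directly by ``lr * weight_decay``
    per step (decoupled from the adaptive gradient estimate), which is the
    behaviour that distinguishes AdamW from L2-regularised Adam.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            step = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * step


class CosineWarmRestarts:
    """SGDR-style schedule: cosine decay from ``base_lr`` to ``eta_min``
    over a period ``t0`` (epochs), restarting with period scaled by
    ``t_mult`` after each cycle. At every restart boundary the rate returns
    exactly to ``base_lr``.
    """

    def __init__(self, base_lr: float, t0: int = 10, t_mult: int = 2,
                 eta_min: float = 1e-6):
        if t0 < 1 or t_mult < 1:
            raise ValueError("t0 and t_mult must be >= 1")
        self.base_lr = base_lr
        self.t0 = t0
        self.t_mult = t_mult
        self.eta_min = eta_min

    def lr_at(self, epoch: int) -> float:
        t, ti = epoch, self.t0
        while t >= ti:
            t -= ti
            ti *= self.t_mult
        return self.eta_min + 0.5 * (self.base_lr - self.eta_min) * (
            1.0 + math.cos(math.pi * t / ti)
        )
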