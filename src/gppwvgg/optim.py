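"""Optimisers and learning-rate schedules for the NumPy layer engine."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class AdamW:
    """Adam with decoupled weight decay (Loshchilov-Hutter update rule)."""

    def __init__(self, params, lr: float = 0.005, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params: list[Parameter] = list(params)
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self._t
        bc2 = 1 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= (self.lr * (update + self.weight_decay * p.data)).astype(p.data.dtype)


class StepDecay:
    """Multiply the learning rate by ``factor`` every ``every`` epochs."""

    def __init__(self, optimizer: AdamW, factor: float = 0.5, every: int = 30):
        if not 0 < factor <= 1:
            raise ValueError(f"decay factor must be in (0, 1], got {factor}")
        if every < 1:
            raise ValueError("decay cadence must be >= 1 epoch")
        self.optimizer = optimizer
        self.factor = factor
        self.every = every
        self._epoch = 0

    def step_epoch(self):
        """Advance one epoch; apply the decay when the cadence divides it."""
        self._epoch += 1
        if self._epoch % self.every == 0:
            self.optimizer.lr *= self.factor
        return self.optimizer.lr
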