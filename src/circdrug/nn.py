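"""Layers, optimizer and learning-rate schedule shared by the neural modules."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .autograd import Tensor

__all__ = ["Linear", "Adam", "one_cycle_lr"]


class Linear:
    """Affine layer with Glorot-uniform weights and zero bias."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Tensor(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class Adam:
    """Adaptive-moment estimation with optional decoupled weight decay."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self._t)
            v_hat = v / (1 - b2**self._t)
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def one_cycle_lr(epoch: int, total_epochs: int, lr_max: float, pct_warmup: float = 0.3) -> float:
    """One-cycle schedule: linear ramp to ``lr_max`` then cosine decay to ~0."""
    warm = max(1, int(total_epochs * pct_warmup))
    if epoch < warm:
        return lr_max * (epoch + 1) / warm
    frac = (epoch - warm) / max(1, total_epochs - warm)
    return lr_max * 0.5 * (1.0 + math.cos(math.pi * frac))
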