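"""Optimizers for the numpy autograd models."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["AdamW", "linear_warmup"]


class AdamW:
    """AdamW with decoupled weight decay.

    Defaults follow common transformer practice (beta1=0.9, beta2=0.999,
    eps=1e-8). Learning rate may be rescaled per step via ``set_lr``.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.base_lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def set_lr(self, lr: float) -> None:
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g**2
            m_hat = self._m[i] / bc1
            v_hat = self._v[i] / bc2
            if self.weight_decay:
                p.data = p.data - self.lr * self.weight_decay * p.data
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def linear_warmup(step: int, total_steps: int, base_lr: float, warmup_frac: float = 0.05) -> float:
    """Linear warmup to ``base_lr`` over the first ``warmup_frac`` of steps,
    constant afterwards."""
    warmup = max(1, int(round(warmup_frac * total_steps)))
    if step < warmup:
        return base_lr * (step + 1) / warmup
    return base_lr
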