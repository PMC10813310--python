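"""Adam optimizer with L2 weight decay and a stepwise-exponential LR schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam (Kingma & Ba) with classic L2 weight decay folded into the gradient.

    Defaults mirror the training recipe used throughout the package:
    lr 1e-4, weight decay 1e-5, betas (0.9, 0.999).
    """

    def __init__(self, params, lr: float = 1e-4, weight_decay: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("lr must be positive")
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def exponential_decay_lr(epoch: int, lr0: float = 1e-4, gamma: float = 0.96, every: int = 2) -> float:
    """lr(e) = lr0 * gamma ** floor(e / every); epochs are 0-based."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return lr0 * gamma ** (epoch // every)
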