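"""AdamW with decoupled weight decay and a cosine-annealing schedule."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW", "cosine_lr"]


def cosine_lr(epoch: int, total_epochs: int, lr_start: float = 1e-4,
              lr_end: float = 1e-6) -> float:
    """Cosine annealing from ``lr_start`` (epoch 0) to ``lr_end`` (last epoch)."""
    if total_epochs <= 1:
        return lr_start
    frac = min(max(epoch / (total_epochs - 1), 0.0), 1.0)
    return lr_end + 0.5 * (lr_start - lr_end) * (1.0 + np.cos(np.pi * frac))


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.wd * p.data)
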