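"""Optimizers and learning-rate scheduling."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class AdamW:
    """Adam with decoupled weight decay (weight decay applied to the
    parameter directly, not through the gradient moments)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.05):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
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
                                 + self.weight_decay * p.data)


class ReduceLROnPlateau:
    """Multiply the lr by `factor` when the monitored score stops improving
    for `patience` successive reports. `mode='max'` monitors a score that
    should increase (e.g. validation SBD)."""

    def __init__(self, optimizer: AdamW, factor: float = 0.1, patience: int = 10,
                 mode: str = "max", min_lr: float = 1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.mode = mode
        self.min_lr = min_lr
        self.best: float | None = None
        self.bad = 0

    def step(self, score: float) -> None:
        improved = (self.best is None
                    or (self.mode == "max" and score > self.best)
                    or (self.mode == "min" and score < self.best))
        if improved:
            self.best = score
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad = 0
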