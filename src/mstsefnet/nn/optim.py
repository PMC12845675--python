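"""Optimisation: AdamW with decoupled weight decay and cosine annealing.

The update rule is the standard decoupled formulation: the L2 penalty is
applied directly to the weights (scaled by the current learning rate)
rather than folded into the gradient, and the adaptive moments follow
Adam with bias correction.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["AdamW", "CosineAnnealingLR"]


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class CosineAnnealingLR:
    """lr(t) = min + (init − min)·(1 + cos(πt/T))/2 for epoch t in [0, T]."""

    def __init__(self, optimizer: AdamW, initial_lr: float, min_lr: float, total_epochs: int):
        if min_lr > initial_lr:
            raise ValueError("min_lr must not exceed initial_lr")
        self.optimizer = optimizer
        self.initial_lr = initial_lr
        self.min_lr = min_lr
        self.total_epochs = max(total_epochs, 1)
        self.epoch = 0
        optimizer.lr = self.lr_at(0)

    def lr_at(self, epoch: int) -> float:
        frac = min(epoch / self.total_epochs, 1.0)
        return self.min_lr + 0.5 * (self.initial_lr - self.min_lr) * (1 + math.cos(math.pi * frac))

    def step(self) -> float:
        """Advance one epoch and set the optimiser lr; returns the new lr."""
        self.epoch += 1
        self.optimizer.lr = self.lr_at(self.epoch)
        return self.optimizer.lr
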