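"""AdamW and learning-rate schedules."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "poly_decay", "cosine_decay"]


class AdamW:
    """Decoupled weight-decay Adam."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-4, lr_scales=None):
        """lr_scales: optional {id(param): scale} for per-parameter groups
        (e.g. slow-moving geometric priors)."""
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        scales = lr_scales or {}
        self.scales = [scales.get(id(p), 1.0) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v, scale in zip(self.params, self.m, self.v, self.scales):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * scale * (upd + self.wd * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def poly_decay(base_lr: float, step: int, total_steps: int, power: float = 0.9) -> float:
    """Polynomial decay: lr = base * (1 - step/total)^power."""
    frac = min(step, total_steps) / max(total_steps, 1)
    return base_lr * (1.0 - frac) ** power


def cosine_decay(base_lr: float, step: int, total_steps: int) -> float:
    frac = min(step, total_steps) / max(total_steps, 1)
    return 0.5 * base_lr * (1.0 + np.cos(np.pi * frac))
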