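"""Adam optimizer and learning-rate schedules."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
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
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class WarmupInverseSqrt:
    """Linear warmup then inverse-square-root decay.

    Calibrated so the rate equals `rate_at_anchor` at `anchor_step`
    (e.g. 0.002 at step 10,000).
    """

    def __init__(self, rate_at_anchor: float, anchor_step: int = 10_000,
                 warmup_steps: int = 400):
        self.warmup = max(1, warmup_steps)
        self.scale = rate_at_anchor * np.sqrt(anchor_step)
        self.peak_step = self.warmup

    def __call__(self, step: int) -> float:
        step = max(1, step)
        peak = self.scale / np.sqrt(self.warmup)
        if step < self.warmup:
            return peak * step / self.warmup
        return self.scale / np.sqrt(step)
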