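"""First-order optimization utilities shared by both trainers.

Adam with an exponentially decaying learning rate, ``lr * dr ** (g / ds)``
at global step ``g`` (decay rate ``dr`` per ``ds`` steps), and global
gradient-norm clipping.
"""

from __future__ import annotations

import numpy as np


def learning_rate(base_lr: float, decay_rate: float, decay_steps: int, step: int) -> float:
    """Learning rate at global step ``step`` under exponential decay."""
    return base_lr * decay_rate ** (step / decay_steps)


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so the global L2 norm is <= max_norm.

    Returns the pre-clip norm.
    """
    total = float(np.sqrt(sum(float((g**2).sum()) for g in grads.values())))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


class Adam:
    """Adam over a flat dict of named parameter arrays (updates in place)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 0.001,
        decay_rate: float = 0.99,
        decay_steps: int = 500,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.decay_rate = decay_rate
        self.decay_steps = decay_steps
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.step_count = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.step_count += 1
        t = self.step_count
        alpha = learning_rate(self.lr, self.decay_rate, self.decay_steps, t)
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**t)
            vhat = self.v[k] / (1 - self.beta2**t)
            p -= alpha * mhat / (np.sqrt(vhat) + self.eps)
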