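"""Adam optimizer over a U-Net's named parameters.

Defaults follow the training setup used throughout the package:
``beta1 = 0.99``, ``beta2 = 0.995``.  Parameters in frozen scopes are
skipped entirely -- neither the weights nor their moment estimates change
while a scope is frozen, so freeze-then-unfreeze schedules behave as two
clean phases.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, model, lr: float, beta1: float = 0.99, beta2: float = 0.995,
                 eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be > 0, got {lr}")
        self.model = model
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name, layer, p in self.model.parameters():
            if not self.model.is_trainable(name):
                continue
            g = layer.grads[p]
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / bc1
            vhat = self.v[name] / bc2
            layer.params[p] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        self.model.zero_grad()
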