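"""Adam optimizer (the DCGAN-standard configuration: lr 2e-4, beta1 0.5)."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(self, model, lr: float = 2e-4, beta1: float = 0.5, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        """Apply one update using the gradients currently stored on the layers."""
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for key, lyr, name in self.model.parameters():
            g = lyr.grads.get(name)
            if g is None:
                continue
            m = self.m.setdefault(key, np.zeros_like(lyr.params[name]))
            v = self.v.setdefault(key, np.zeros_like(lyr.params[name]))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            lyr.params[name] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
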