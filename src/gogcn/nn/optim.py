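"""Adaptive-moment (Adam) optimizer over named parameter triples."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict = {}
        self._v: dict = {}

    def step(self, parameters) -> None:
        """Update each (name, value, grad) triple in place."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for name, val, grad in parameters:
            m = self._m.setdefault(name, np.zeros_like(val))
            v = self._v.setdefault(name, np.zeros_like(val))
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            val -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
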