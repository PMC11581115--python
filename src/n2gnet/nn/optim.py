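"""Adaptive-moment (Adam) optimizer over named parameter dictionaries."""

from __future__ import annotations

import numpy as np


class Adam:
    """Standard Adam with bias-corrected first/second moments.

    Parameters are referenced in place through ``(name, param, grad)``
    triples supplied by the model, so a single optimizer instance drives the
    whole network.
    """

    def __init__(self, learning_rate: float = 1e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, named_params) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for name, param, grad in named_params:
            m = self._m.setdefault(name, np.zeros_like(param))
            v = self._v.setdefault(name, np.zeros_like(param))
            m += (1.0 - b1) * (grad - m)
            v += (1.0 - b2) * (grad * grad - v)
            param -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
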