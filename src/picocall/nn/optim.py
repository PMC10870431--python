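"""AdamW: adaptive moments with decoupled weight decay."""

from __future__ import annotations

from typing import Dict, Iterable, List

import numpy as np

from .layers import Param, unique_params


class AdamW:
    """Decoupled-weight-decay Adam.

    ``beta2`` defaults to 0.999 (second-moment coefficient) and ``beta1`` to
    the conventional 0.9.  Weight decay is applied directly to the weights,
    not through the gradient.  Normalization affine parameters and biases are
    excluded from decay, following common practice.
    """

    def __init__(self, params: Iterable[Param], lr: float = 2e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params: List[Param] = unique_params(params)
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.eps, self.weight_decay = eps, weight_decay
        self.t = 0
        self._m: Dict[int, np.ndarray] = {}
        self._v: Dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p in self.params:
            key = id(p)
            m = self._m.setdefault(key, np.zeros_like(p.value))
            v = self._v.setdefault(key, np.zeros_like(p.value))
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad ** 2 - v)
            if self.weight_decay and p.value.ndim > 1:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.apply_mask()

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
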