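"""Optimisers and weight constraints."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class RMSprop:
    """RMSprop with optional coupled L2 penalty.

    Square-gradient smoothing ``alpha`` 0.99 and ``eps`` 1e-8; no momentum.
    The L2 term is added to the gradient (penalty formulation), so it
    interacts with the adaptive denominator the usual way.
    """

    def __init__(self, params: list[Tensor], lr: float = 0.002,
                 alpha: float = 0.99, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.alpha = alpha
        self.eps = eps
        self.weight_decay = weight_decay
        self._sq = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, sq in zip(self.params, self._sq):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            sq *= self.alpha
            sq += (1.0 - self.alpha) * g * g
            p.data -= self.lr * g / (np.sqrt(sq) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def apply_max_norm(weights: list[Tensor], max_norm: float) -> None:
    """Clamp the L2 norm of each output filter to ``max_norm`` in place.

    For a conv weight (Co, ...) or linear weight (in, out) the norm is
    taken per output unit, Keras ``max_norm`` style.
    """
    if max_norm <= 0:
        raise ValueError("max_norm must be positive")
    for w in weights:
        a = w.data
        if a.ndim == 2:  # linear: (in, out) -> per column
            norms = np.sqrt((a * a).sum(axis=0, keepdims=True))
            np.multiply(a, np.minimum(1.0, max_norm / np.maximum(norms, 1e-12)),
                        out=a)
        elif a.ndim >= 3:  # conv: (Co, ...) or depthwise (C, kh, kw)
            flat = a.reshape(a.shape[0], -1)
            norms = np.sqrt((flat * flat).sum(axis=1))
            scale = np.minimum(1.0, max_norm / np.maximum(norms, 1e-12))
            a *= scale.reshape((-1,) + (1,) * (a.ndim - 1))
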