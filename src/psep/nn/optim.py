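"""Adagrad optimizer (per-parameter adaptive learning rates)."""

from __future__ import annotations

import numpy as np


class Adagrad:
    """Accumulates squared gradients; step size lr / sqrt(accum + eps).

    Accumulators start at 0.1 (the TensorFlow convention) rather than 0,
    which bounds the very first steps to ~3 lr instead of lr * sign(g) and
    avoids an early gradient spike throttling the whole run.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        eps: float = 1e-10,
        initial_accumulator_value: float = 0.1,
    ):
        self.params = params
        self.lr = float(lr)
        self.eps = eps
        self._accum = {
            k: np.full_like(v, initial_accumulator_value, dtype=np.float32)
            for k, v in params.items()
        }

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for name, g in grads.items():
            acc = self._accum[name]
            g32 = g.astype(np.float32, copy=False)
            acc += g32 * g32
            self.params[name] -= self.lr * g32 / (np.sqrt(acc) + self.eps)
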