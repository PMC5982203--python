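"""Penalty-weighted cross-entropy objective.

The per-pixel loss is

    E = -(1/K) * sum_n sum_k  p_n * t_nk * ln(y_nk)

with N pixels, K classes, one-hot targets t_nk, predicted probabilities
y_nk and a per-pixel weight p_n.  The weights implement two ideas: a value
of 0 on the halo ring around annotated marks removes those pixels from the
loss entirely (annotation jitter is not punished), while a large value on
penalty regions makes repeating the baseline model's false positives
expensive.

Two normalizations are exposed.  ``literal_scaling=True`` keeps the 1/K
constant above; the default additionally divides by sum(p_n), giving a
weighted mean that is independent of crop size (the constant only rescales
the effective learning rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7  # probability clip before the logarithm


@dataclass(frozen=True)
class LossValue:
    """Non-negative scalar objective value."""

    E: float

    def __post_init__(self):
        if self.E < 0:
            raise ValueError("loss must be non-negative")

    def __float__(self) -> float:
        return self.E


def _as_probs(probs) -> np.ndarray:
    p = np.asarray(getattr(probs, "probabilities", probs), dtype=np.float64)
    if p.ndim != 3:
        raise ValueError("probabilities must be (H, W, K)")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def weighted_cross_entropy(probs, label, weights, literal_scaling: bool = False) -> LossValue:
    """Evaluate the penalty-weighted cross entropy.

    Parameters
    ----------
    probs
        :class:`~psep.nn.fcn.SegmentationOutput` or (H, W, K) array.
    label
        :class:`~psep.annotations.LabelMask` or (H, W) integer class map.
    weights
        :class:`~psep.annotations.WeightMask` or (H, W) array of p_n.
    literal_scaling
        If True, scale by 1/K only; otherwise divide additionally by
        sum(p_n) (the default used during training).
    """
    y = _as_probs(probs)
    t = np.asarray(getattr(label, "values", label))
    p = np.asarray(getattr(weights, "values", weights), dtype=np.float64)
    if t.shape != y.shape[:2] or p.shape != y.shape[:2]:
        raise ValueError(
            f"shape mismatch: probs {y.shape[:2]}, label {t.shape}, weights {p.shape}"
        )
    k = y.shape[2]
    y_target = np.take_along_axis(y, t[..., None].astype(np.intp), axis=2)[..., 0]
    total = -(p * np.log(np.clip(y_target, EPS, 1.0))).sum() / k
    if not literal_scaling:
        psum = p.sum()
        total = total / psum if psum > 0 else 0.0
    return LossValue(float(max(total, 0.0)))


def softmax_cross_entropy_grad(
    logits: np.ndarray, label: np.ndarray, weights: np.ndarray, literal_scaling: bool = False
) -> tuple[float, np.ndarray]:
    """Loss and d(loss)/d(logits) for the combined softmax + weighted CE.

    ``logits`` is (K, H, W); gradient for class k at pixel n is
    scale * p_n * (y_nk - t_nk), with scale = 1/K (literal) or
    1/(K * sum p_n) (mean).
    """
    z = logits.astype(np.float64)
    z -= z.max(axis=0, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=0, keepdims=True)
    k = z.shape[0]
    t = np.asarray(getattr(label, "values", label))
    p = np.asarray(getattr(weights, "values", weights), dtype=np.float64)

    y_target = np.take_along_axis(y, t[None].astype(np.intp), axis=0)[0]
    scale = 1.0 / k
    if not literal_scaling:
        psum = p.sum()
        scale /= psum if psum > 0 else 1.0
    loss = -scale * (p * np.log(np.clip(y_target, EPS, 1.0))).sum()

    dlogits = y
    np.put_along_axis(dlogits, t[None].astype(np.intp), y_target - 1.0, axis=0)
    dlogits *= scale * p[None]
    return float(loss), dlogits
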