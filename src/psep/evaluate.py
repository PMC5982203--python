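"""Point-matching evaluation, model-selection grid and count regression.

Detections and annotations are compared as point sets: a one-to-one
assignment pairs each detection with at most one annotation within a
distance tolerance, maximizing the number of pairs and, among such
assignments, minimizing the total paired distance.  Matched pairs are true
positives, unmatched detections false positives, unmatched annotations
false negatives, from which

    P = TP / (TP + FP),   R = TP / (TP + FN),   F = 2 P R / (P + R).

Pixel-wise accuracy is deliberately not reported: with PSEP pixels this
rare, predicting pure background already scores ~99%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import r2_score


def _as_points(obj) -> np.ndarray:
    pts = getattr(obj, "points", obj)
    arr = np.asarray(list(pts), dtype=float)
    return arr.reshape(-1, 2)


@dataclass(frozen=True)
class MatchResult:
    """One-to-one pairing of detections and annotations."""

    matched_pairs: tuple[tuple[tuple[float, float], tuple[float, float]], ...]
    TP: int
    FP: int
    FN: int
    tolerance: float

    @property
    def total_distance(self) -> float:
        return float(
            sum(np.hypot(d[0] - a[0], d[1] - a[1]) for d, a in self.matched_pairs)
        )


@dataclass(frozen=True)
class MetricsRecord:
    """Precision / recall / F1 for one (penalty weight, threshold) cell."""

    P: float
    R: float
    F: float
    penalty_weight: float | None = None
    softmax_threshold: float | None = None


@dataclass(frozen=True)
class GridResult:
    """Metrics over the penalty-weight x softmax-threshold model grid."""

    records: tuple[MetricsRecord, ...]

    @property
    def best(self) -> MetricsRecord:
        """Highest F; ties go to the lower threshold, then lower weight."""
        return max(
            self.records,
            key=lambda r: (r.F, -(r.softmax_threshold or 0), -(r.penalty_weight or 0)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "penalty_weight": r.penalty_weight,
                    "softmax_threshold": r.softmax_threshold,
                    "P": r.P,
                    "R": r.R,
                    "F": r.F,
                }
                for r in self.records
            ]
        )


def match_points(detections, annotations, tolerance: float = 20.0) -> MatchResult:
    """Optimal one-to-one matching of detections to annotations.

    Among assignments whose every pair lies within ``tolerance`` (Euclidean,
    inclusive), the pair count is maximized first and the total paired
    distance minimized second.  Default tolerance equals the 20-px mark
    diameter, i.e. points whose annotation disks could touch.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    det = _as_points(detections)
    ann = _as_points(annotations)
    n_det, n_ann = len(det), len(ann)
    if n_det == 0 or n_ann == 0:
        return MatchResult((), 0, n_det, n_ann, tolerance)

    dist = cdist(det, ann)
    feasible = dist <= tolerance
    # infeasible pairs get a cost so large that dropping one real match can
    # never pay for it -> the assignment maximizes matches first
    big = tolerance * min(n_det, n_ann) + 1.0
    cost = np.where(feasible, dist, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = tuple(
        (tuple(det[i]), tuple(ann[j])) for i, j in zip(rows, cols) if feasible[i, j]
    )
    tp = len(pairs)
    return MatchResult(pairs, tp, n_det - tp, n_ann - tp, tolerance)


def compute_metrics(
    match: MatchResult,
    penalty_weight: float | None = None,
    softmax_threshold: float | None = None,
) -> MetricsRecord:
    """Precision, recall and F1 from TP/FP/FN counts.

    Empty denominators follow the perfect-by-convention rule: P = 1 with no
    detections, R = 1 with no annotations (an empty scene predicted empty
    scores 1 everywhere); F = 0 when P + R = 0.
    """
    return metrics_from_counts(match.TP, match.FP, match.FN, penalty_weight, softmax_threshold)


def metrics_from_counts(
    tp: int,
    fp: int,
    fn: int,
    penalty_weight: float | None = None,
    softmax_threshold: float | None = None,
) -> MetricsRecord:
    p = tp / (tp + fp) if tp + fp > 0 else 1.0
    r = tp / (tp + fn) if tp + fn > 0 else 1.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return MetricsRecord(p, r, f, penalty_weight, softmax_threshold)


def evaluate_detections(
    prob_maps: Sequence,
    annotations: Sequence,
    threshold: float,
    tolerance: float,
    min_area: int = 1,
) -> MetricsRecord:
    """Micro-averaged P/R/F of probability maps against point annotations:
    TP/FP/FN are summed over images before the ratios are taken."""
    from .detect import detect

    tp = fp = fn = 0
    for probs, ann in zip(prob_maps, annotations):
        m = match_points(detect(probs, threshold, min_area), ann, tolerance)
        tp, fp, fn = tp + m.TP, fp + m.FP, fn + m.FN
    return metrics_from_counts(tp, fp, fn, softmax_threshold=threshold)


def grid_evaluate(
    trainer: Callable[[float], object],
    eval_set: Sequence[tuple],
    weights: Sequence[float],
    thresholds: Sequence[float],
    tolerance: float = 20.0,
    min_area: int = 1,
) -> GridResult:
    """Sweep the penalty-weight x softmax-threshold model grid.

    ``trainer(weight)`` returns a trained model (anything with a
    ``predict(image)`` method, or a plain callable image -> probabilities);
    each model is evaluated at every threshold on ``eval_set``, a sequence
    of (image, PointAnnotation) pairs.  The canonical grid of 3 weights
    {0, 50, 75} and 9 thresholds 0.1..0.9 yields 27 cells.
    """
    if len(list(weights)) == 0 or len(list(thresholds)) == 0:
        raise ValueError("weights and thresholds must be non-empty")
    records = []
    for w in weights:
        model = trainer(w)
        predict = model.predict if hasattr(model, "predict") else model
        prob_maps = [predict(img) for img, _ in eval_set]
        anns = [ann for _, ann in eval_set]
        for t in thresholds:
            rec = evaluate_detections(prob_maps, anns, t, tolerance, min_area)
            records.append(
                MetricsRecord(rec.P, rec.R, rec.F, penalty_weight=w, softmax_threshold=t)
            )
    return GridResult(tuple(records))


def count_regression(predicted_counts, annotated_counts) -> float:
    """Coefficient of determination R^2 of predicted vs. annotated counts,
    computed as 1 - SS_res / SS_tot with the annotated counts as reference."""
    pred = np.asarray(list(predicted_counts), dtype=float)
    ann = np.asarray(list(annotated_counts), dtype=float)
    if pred.shape != ann.shape:
        raise ValueError("count lists must have equal length")
    if len(ann) < 2:
        raise ValueError("need at least two count pairs")
    if np.ptp(ann) == 0:
        raise ValueError("annotated counts have zero variance")
    return float(r2_score(ann, pred))


def render_matches(image, detections, annotations, match: MatchResult, path) -> None:
    """Overlay the match outcome on the image with the usual color code:
    pink = true prediction (with a white line to its annotation),
    blue = false detection, red = missed annotation."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    det = [tuple(p) for p in _as_points(detections)]
    ann = [tuple(p) for p in _as_points(annotations)]
    matched_det = {d for d, _ in match.matched_pairs}
    matched_ann = {a for _, a in match.matched_pairs}
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.asarray(image))
    for d, a in match.matched_pairs:
        ax.plot([d[1], a[1]], [d[0], a[0]], color="white", lw=1)
        ax.plot(d[1], d[0], "o", color="#ff69b4", ms=5)
    for r, c in det:
        if (r, c) not in matched_det:
            ax.plot(c, r, "o", color="blue", ms=5)
    for r, c in ann:
        if (r, c) not in matched_ann:
            ax.plot(c, r, "o", color="red", ms=5)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
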