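"""Desk-scale reference experiments on synthetic fields.

Two protocols mirror the headline analyses of a PSEP-detection study at
sizes a single CPU core handles in minutes:

* :func:`penalty_benchmark` -- does adding penalty regions help?  A
  penalty-free primary model is trained on "hard" scenes (seed-drill rows,
  overlapping leaves, leaf-tip / residue distractors), its false positives
  become penalty regions, a copy is retrained with those regions
  up-weighted, and both models are compared by best-threshold F and by
  false positives at distractor sites.
* :func:`count_recovery_benchmark` -- can the detector count?  A model is
  trained on "easy" scenes and its per-image detection counts on scenes
  spanning the whole density range are regressed against the true counts.

All randomness (scene content, initialization, crops) derives from one
master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detect import detect
from .evaluate import MetricsRecord, count_regression, match_points, metrics_from_counts
from .nn import FCNModel, ModelSpec, TrainingSchedule
from .pipeline import PenaltyPipeline, PenaltyTrainingConfig
from .synthetic import SyntheticScene, easy_spec, generate_scene, hard_spec

#: Desk-scale annotation geometry: 6-px marks on 128-px scenes play the
#: role of 20-px marks on field imagery; halo = mark radius.
MARK_DIAMETER = 6.0
MATCH_TOLERANCE = 6.0
EXCLUSION_RADIUS = 12.0  # keeps penalties beyond leaf length from true bases
THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

_MINI = ModelSpec(backbone="mini", channels=(12, 24, 48))


def _scene_batch(rng, n, make, lo, hi, **kw):
    return [
        generate_scene(make(int(rng.integers(lo, hi)), seed=int(rng.integers(2**31)), **kw))
        for _ in range(n)
    ]


def threshold_sweep(
    model: FCNModel,
    scenes: list[SyntheticScene],
    thresholds=THRESHOLDS,
    tolerance: float = MATCH_TOLERANCE,
) -> dict[float, MetricsRecord]:
    """Micro-averaged P/R/F of a model on scenes at each threshold."""
    prob_maps = [model.predict(s.image) for s in scenes]
    out = {}
    for thr in thresholds:
        tp = fp = fn = 0
        for probs, scene in zip(prob_maps, scenes):
            m = match_points(detect(probs, thr), scene.truth, tolerance)
            tp, fp, fn = tp + m.TP, fp + m.FP, fn + m.FN
        out[thr] = metrics_from_counts(tp, fp, fn, softmax_threshold=thr)
    return out


def false_positives_at_distractors(
    model: FCNModel,
    scenes: list[SyntheticScene],
    threshold: float,
    tolerance: float = MATCH_TOLERANCE,
) -> int:
    """Unmatched detections within ``tolerance`` of a known distractor site."""
    n = 0
    for scene in scenes:
        dets = detect(model.predict(scene.image), threshold)
        m = match_points(dets, scene.truth, tolerance)
        matched = {d for d, _ in m.matched_pairs}
        for p in dets.points:
            if p in matched:
                continue
            if any(
                np.hypot(p[0] - q[0], p[1] - q[1]) <= tolerance
                for q in scene.distractor_points
            ):
                n += 1
    return n


@dataclass(frozen=True)
class PenaltyBenchmarkResult:
    baseline_best: MetricsRecord
    penalty_best: MetricsRecord
    baseline_fp_at_distractors: int
    penalty_fp_at_distractors: int
    penalty_weight: float
    n_penalty_pixels: int

    @property
    def f_gain(self) -> float:
        return self.penalty_best.F - self.baseline_best.F


def penalty_benchmark(
    seed: int = 1,
    n_train: int = 100,
    n_eval: int = 50,
    penalty_weight: float = 50.0,
) -> PenaltyBenchmarkResult:
    """Penalty-region study on the hard synthetic preset.

    Trains the primary model for 8 epochs (Adagrad, lr 0.05, crops 96),
    derives penalty regions from its confident false responses, retrains a
    copy for 8 gentler epochs (lr 0.01) with the penalty weight applied,
    and evaluates both models over the nine softmax thresholds.
    """
    rng = np.random.default_rng(seed)
    train_scenes = _scene_batch(rng, n_train, hard_spec, 6, 16)
    eval_scenes = _scene_batch(rng, n_eval, hard_spec, 6, 16)
    cfg = PenaltyTrainingConfig(
        mark_diameter=MARK_DIAMETER,
        exclusion_radius=EXCLUSION_RADIUS,
        model_spec=_MINI,
        schedule=TrainingSchedule(
            epochs=8, initial_lr=0.05, lr_drop_epochs=(6, 7), crop_size=96, seed=seed
        ),
        retrain_schedule=TrainingSchedule(
            epochs=8, initial_lr=0.01, lr_drop_epochs=(6, 7), crop_size=96, seed=seed + 1
        ),
    )
    pipe = PenaltyPipeline([(s.image, s.truth) for s in train_scenes], cfg)
    baseline = pipe.baseline
    penalty_model, _ = pipe.train_model(penalty_weight)

    sweep0 = threshold_sweep(baseline, eval_scenes)
    sweepw = threshold_sweep(penalty_model, eval_scenes)
    best0 = max(sweep0.values(), key=lambda r: (r.F, -r.softmax_threshold))
    bestw = max(sweepw.values(), key=lambda r: (r.F, -r.softmax_threshold))
    return PenaltyBenchmarkResult(
        baseline_best=best0,
        penalty_best=bestw,
        baseline_fp_at_distractors=false_positives_at_distractors(
            baseline, eval_scenes, best0.softmax_threshold
        ),
        penalty_fp_at_distractors=false_positives_at_distractors(
            penalty_model, eval_scenes, bestw.softmax_threshold
        ),
        penalty_weight=penalty_weight,
        n_penalty_pixels=int(sum(p.values.sum() for p in pipe.penalty_regions)),
    )


@dataclass(frozen=True)
class CountRecoveryResult:
    r_squared: float
    true_counts: tuple[int, ...]
    predicted_counts: tuple[int, ...]


def count_recovery_benchmark(
    seed: int = 1,
    n_train: int = 40,
    n_eval: int = 30,
    max_count: int = 110,
    threshold: float = 0.4,
) -> CountRecoveryResult:
    """Count-recovery study on the easy synthetic preset.

    Evaluation scenes are 256x256 with true counts evenly spanning
    0..``max_count`` (all eleven ranges of the average-60 scheme); the
    model is trained on denser 128x128 easy scenes.
    """
    rng = np.random.default_rng(seed)
    train_scenes = _scene_batch(rng, n_train, easy_spec, 4, 16, image_shape=(128, 128))
    counts = np.linspace(0, max_count, n_eval).round().astype(int)
    eval_scenes = [
        generate_scene(
            easy_spec(int(c), image_shape=(256, 256), seed=int(rng.integers(2**31)))
        )
        for c in counts
    ]
    cfg = PenaltyTrainingConfig(
        mark_diameter=MARK_DIAMETER,
        model_spec=_MINI,
        schedule=TrainingSchedule(
            epochs=10, initial_lr=0.05, lr_drop_epochs=(8, 9), crop_size=96, seed=seed
        ),
    )
    pipe = PenaltyPipeline([(s.image, s.truth) for s in train_scenes], cfg)
    model = pipe.baseline
    predicted = tuple(len(detect(model.predict(s.image), threshold)) for s in eval_scenes)
    true = tuple(s.plant_count for s in eval_scenes)
    return CountRecoveryResult(
        r_squared=count_regression(predicted, true),
        true_counts=true,
        predicted_counts=predicted,
    )
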