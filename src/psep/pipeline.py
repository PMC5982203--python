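"""Two-pass penalty training workflow.

The penalty mechanism needs a bootstrap: first a *baseline* model is trained
with no penalty regions (weight masks are 1 everywhere except the
non-punishing halo).  Its false-positive responses away from the annotated
marks -- typically leaf tips, weeds and residue -- become the penalty
regions, and the final model is retrained from scratch with those regions
up-weighted in the loss.  Penalty regions are derived once from the
baseline, not re-derived per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotations import (
    LabelMask,
    PenaltyRegionMask,
    PointAnnotation,
    build_weight_mask,
    derive_penalty_regions,
    rasterize_marks,
)
from .nn import FCNModel, LossLog, ModelSpec, TrainingSchedule, build_model, train


@dataclass(frozen=True)
class PenaltyTrainingConfig:
    """Settings shared by the baseline and penalty-weighted passes.

    ``halo_radius`` defaults to the mark radius (the smallest scale over
    which annotation jitter is plausible); ``exclusion_radius`` defaults to
    mark radius + halo radius so derived penalties never abut true points
    (weights >= 100 are known not to converge when they do).
    """

    mark_diameter: float = 20.0
    halo_radius: float | None = None
    exclusion_radius: float | None = None
    prob_threshold: float = 0.5
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)
    retrain_schedule: TrainingSchedule | None = None
    literal_scaling: bool = False

    @property
    def halo(self) -> float:
        return self.mark_diameter / 2 if self.halo_radius is None else self.halo_radius

    @property
    def exclusion(self) -> float:
        if self.exclusion_radius is None:
            return self.mark_diameter / 2 + self.halo
        return self.exclusion_radius


class PenaltyPipeline:
    """Trains PSEP segmentation models at any penalty weight.

    Parameters
    ----------
    training_set
        Sequence of ``(image, PointAnnotation)`` pairs; images are
        (H, W, 3) floats in [0, 1].
    """

    def __init__(self, training_set: Sequence[tuple], config: PenaltyTrainingConfig):
        self.config = config
        self.images = [np.asarray(img, dtype=np.float32) for img, _ in training_set]
        self.annotations: list[PointAnnotation] = [
            PointAnnotation(
                getattr(ann, "points", ann), config.mark_diameter, img.shape[:2]
            )
            for img, ann in zip(self.images, (a for _, a in training_set))
        ]
        self.labels: list[LabelMask] = [rasterize_marks(a) for a in self.annotations]
        self._baseline: FCNModel | None = None
        self._baseline_log: LossLog | None = None
        self._penalties: list[PenaltyRegionMask] | None = None

    # -- stages -------------------------------------------------------------

    def _dataset(self, penalty_weight: float, penalties) -> list[tuple]:
        cfg = self.config
        return [
            (img, lab, build_weight_mask(lab, pen, penalty_weight, cfg.halo))
            for img, lab, pen in zip(self.images, self.labels, penalties)
        ]

    @property
    def baseline(self) -> FCNModel:
        """The penalty-free model (trained on first access)."""
        if self._baseline is None:
            empty = [PenaltyRegionMask.empty(lab.shape) for lab in self.labels]
            # weight 1 everywhere except the halo: penalty mask empty
            dataset = self._dataset(1.0, empty)
            model = build_model(self.config.model_spec, seed=self.config.schedule.seed)
            self._baseline_log = train(
                model, dataset, self.config.schedule, self.config.literal_scaling
            )
            self._baseline = model
        return self._baseline

    @property
    def penalty_regions(self) -> list[PenaltyRegionMask]:
        """Per-image penalty regions from the baseline's false positives."""
        if self._penalties is None:
            cfg = self.config
            model = self.baseline
            self._penalties = [
                derive_penalty_regions(
                    model.predict(img), lab, cfg.exclusion, cfg.prob_threshold
                )
                for img, lab in zip(self.images, self.labels)
            ]
        return self._penalties

    def train_model(self, penalty_weight: float) -> tuple[FCNModel, LossLog]:
        """Train a model at the given penalty weight.

        Weight 0 is the primary (penalty-free) network itself; positive
        weights retrain a copy of it with the derived penalty regions
        up-weighted in the loss -- the two-pass protocol.
        """
        if penalty_weight == 0:
            _ = self.baseline
            return self._baseline, self._baseline_log
        dataset = self._dataset(penalty_weight, self.penalty_regions)
        model = self.baseline.copy()
        schedule = self.config.retrain_schedule or self.config.schedule
        log = train(model, dataset, schedule, self.config.literal_scaling)
        return model, log

    def trainer(self):
        """``weight -> model`` callable for :func:`psep.evaluate.grid_evaluate`."""
        return lambda w: self.train_model(w)[0]
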