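"""Training loop: random crops per epoch, Adagrad, stepped learning rate.

The field-scale defaults follow the reference protocol for this detector:
40 epochs of single-image updates on random 1500x1500 crops with Adagrad at
learning rate 1e-3, halved after epochs 32 and 36.  Desk-scale runs shrink
the crop, epoch count and learning rate through the same schedule object.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fcn import FCNModel
from .loss import softmax_cross_entropy_grad
from .optim import Adagrad


@dataclass(frozen=True)
class TrainingSchedule:
    epochs: int = 40
    initial_lr: float = 1e-3
    lr_drop_epochs: tuple[int, ...] = (32, 36)
    lr_drop_factor: float = 2.0
    crop_size: int = 1500
    seed: int = 0
    optimizer: str = "adagrad"

    def learning_rate(self, epoch: int) -> float:
        """Learning rate during 1-based ``epoch`` (drops apply after the
        listed epochs complete, e.g. epoch 33 runs at initial_lr / 2)."""
        n_drops = sum(1 for d in self.lr_drop_epochs if epoch > d)
        return self.initial_lr / self.lr_drop_factor**n_drops


@dataclass
class LossLog:
    """Per-epoch record of (epoch, learning rate, mean training loss)."""

    records: list[tuple[int, float, float]] = field(default_factory=list)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "lr", "mean_loss"])
            writer.writerows(self.records)

    @property
    def mean_losses(self) -> list[float]:
        return [r[2] for r in self.records]


def _random_crop(rng, image, label, weights, crop: int):
    h, w = label.shape
    if crop > h or crop > w:
        raise ValueError(f"crop size {crop} larger than image {h}x{w}")
    r0 = int(rng.integers(0, h - crop + 1))
    c0 = int(rng.integers(0, w - crop + 1))
    sl = (slice(r0, r0 + crop), slice(c0, c0 + crop))
    return image[sl], label[sl], weights[sl]


def train(
    model: FCNModel,
    dataset: Sequence[tuple],
    schedule: TrainingSchedule,
    literal_scaling: bool = False,
) -> LossLog:
    """Train ``model`` in place on (image, label, weight) triples.

    Images are (H, W, 3) floats in [0, 1]; labels and weights may be the
    mask dataclasses or bare arrays.  Every source of randomness (sample
    order, crop positions) derives from ``schedule.seed``, so a fixed seed
    and dataset reproduce the loss trajectory exactly on a fixed-threading
    run.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    triples = [
        (
            np.asarray(img, dtype=np.float32),
            np.asarray(getattr(lab, "values", lab)),
            np.asarray(getattr(wgt, "values", wgt), dtype=np.float32),
        )
        for img, lab, wgt in dataset
    ]
    for img, lab, wgt in triples:
        if img.shape[:2] != lab.shape or lab.shape != wgt.shape:
            raise ValueError("image/label/weight shapes disagree")

    rng = np.random.default_rng(schedule.seed)
    opt = Adagrad(model.named_params(), lr=schedule.initial_lr)
    log = LossLog()
    for epoch in range(1, schedule.epochs + 1):
        opt.lr = schedule.learning_rate(epoch)
        order = rng.permutation(len(triples))
        losses = []
        for idx in order:
            img, lab, wgt = triples[idx]
            ci, cl, cw = _random_crop(rng, img, lab, wgt, schedule.crop_size)
            logits = model.forward_logits(ci)
            loss, dlogits = softmax_cross_entropy_grad(logits, cl, cw, literal_scaling)
            model.backward(dlogits)
            opt.step(model.named_grads())
            losses.append(loss)
        log.records.append((epoch, opt.lr, float(np.mean(losses))))
    return log
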