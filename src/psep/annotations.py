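"""Point annotations, label masks, penalty regions and loss-weight masks.

A PSEP (plant stem emerging point) annotation is a set of pixel coordinates
marking where plant stems exit the soil.  For training a per-pixel classifier
the points are rasterized into filled disks (the annotation marks), and a
per-pixel weight mask is assembled that

* zeroes the loss on a "non-punishing" halo ring around each mark, so small
  annotation jitter is not punished, and
* up-weights the loss on *penalty regions*: places where a baseline model
  (trained without penalties) produced false-positive responses, typically
  leaf tips, weeds and plant residue that resemble emergence points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

#: Mask encoding used on disk: background / PSEP mark / penalty region,
#: with the halo ring added as 3 in the extended debug encoding.
BACKGROUND, PSEP, PENALTY, HALO = 0, 1, 2, 3


@dataclass(frozen=True)
class PointAnnotation:
    """Point marks for one image.

    Parameters
    ----------
    points
        ``(row, col)`` pixel coordinates, 0-based, pixel-center convention.
        May be empty.
    mark_diameter
        Diameter in pixels of the filled disk drawn around each point
        (field-scale annotations use 20 px).
    image_shape
        ``(height, width)`` of the annotated image.
    """

    points: tuple[tuple[float, float], ...]
    mark_diameter: float = 20.0
    image_shape: tuple[int, int] = (0, 0)

    def __post_init__(self):
        object.__setattr__(self, "points", tuple((float(r), float(c)) for r, c in self.points))
        if self.mark_diameter <= 0:
            raise ValueError("mark_diameter must be positive")
        h, w = self.image_shape
        for r, c in self.points:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"point ({r}, {c}) outside image bounds {self.image_shape}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def mark_radius(self) -> float:
        return self.mark_diameter / 2.0


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel class target: 0 = background, 1 = PSEP mark."""

    values: np.ndarray
    mark_diameter: float = 20.0

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or not np.isin(v, (0, 1)).all():
            raise ValueError("label mask must be 2-D with entries in {0, 1}")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def one_hot(self) -> np.ndarray:
        """(H, W, 2) one-hot target over the (background, PSEP) classes."""
        t = np.zeros(self.values.shape + (2,), dtype=np.float64)
        t[..., 0] = self.values == 0
        t[..., 1] = self.values == 1
        return t


@dataclass(frozen=True)
class PenaltyRegionMask:
    """Boolean mask of extra-penalized pixels (baseline false positives)."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "PenaltyRegionMask":
        return cls(np.zeros(shape, dtype=bool))


@dataclass(frozen=True)
class WeightMask:
    """Per-pixel loss weight p_n: 0 on the halo ring, ``penalty_weight`` on
    penalty regions, 1 elsewhere (including inside the mark disks)."""

    values: np.ndarray
    penalty_weight: float = 0.0
    halo_radius: float = 10.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if (v < 0).any():
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def rasterize_marks(annotation: PointAnnotation) -> LabelMask:
    """Rasterize point marks as filled disks.

    A pixel is part of a mark iff its center lies within ``mark_diameter / 2``
    (Euclidean, boundary inclusive) of any annotated point; overlapping disks
    merge.
    """
    h, w = annotation.image_shape
    out = np.zeros((h, w), dtype=np.uint8)
    r = annotation.mark_radius
    for pr, pc in annotation.points:
        r0, r1 = max(0, int(np.floor(pr - r))), min(h - 1, int(np.ceil(pr + r)))
        c0, c1 = max(0, int(np.floor(pc - r))), min(w - 1, int(np.ceil(pc + r)))
        rows = np.arange(r0, r1 + 1)[:, None]
        cols = np.arange(c0, c1 + 1)[None, :]
        inside = (rows - pr) ** 2 + (cols - pc) ** 2 <= r * r
        out[r0 : r1 + 1, c0 : c1 + 1] |= inside.astype(np.uint8)
    return LabelMask(out, mark_diameter=annotation.mark_diameter)


def parse_overlay_layer(
    overlay_image: np.ndarray,
    mark_diameter: float = 20.0,
    red_tolerance: float = 30.0,
    eccentricity_threshold: float = 0.9,
) -> PointAnnotation:
    """Recover point marks from a painted overlay layer.

    The overlay carries pure-red filled circles (one per PSEP) on a
    transparent or neutral background, as produced by marking points in a
    separate image-editor layer.  One point is returned per connected red
    component, at the component centroid.  Components that do not look like
    disks (eccentricity above ``eccentricity_threshold``) trigger a warning
    but still contribute their centroid.
    """
    img = np.asarray(overlay_image)
    if img.ndim != 3 or img.shape[2] not in (3, 4):
        raise ValueError("overlay must be an RGB or RGBA image")
    rgb = img[..., :3].astype(np.float64)
    red = np.abs(rgb - np.array([255.0, 0.0, 0.0])).max(axis=-1) <= red_tolerance
    if img.shape[2] == 4:
        red &= img[..., 3] > 0

    labels = measure.label(red, connectivity=2)
    points = []
    for region in measure.regionprops(labels):
        if region.eccentricity > eccentricity_threshold:
            warnings.warn(
                f"overlay component at {region.centroid} is not disk-like "
                f"(eccentricity {region.eccentricity:.2f})",
                stacklevel=2,
            )
        points.append(region.centroid)
    return PointAnnotation(
        points=tuple(points), mark_diameter=mark_diameter, image_shape=red.shape
    )


def derive_penalty_regions(
    baseline_probs: np.ndarray,
    label: LabelMask,
    exclusion_radius: float = 20.0,
    prob_threshold: float = 0.5,
) -> PenaltyRegionMask:
    """Turn a baseline model's false positives into penalty regions.

    Pixels whose baseline PSEP probability reaches ``prob_threshold`` are
    candidate faults; candidates within ``exclusion_radius`` of any annotated
    mark disk are discarded (subtracting the true marks), leaving only
    responses away from real emergence points -- leaf tips, residue and other
    lookalikes.

    Parameters
    ----------
    baseline_probs
        (H, W) PSEP-channel probability of the penalty-free baseline model,
        or an (H, W, 2) probability grid whose channel 1 is PSEP.
    """
    probs = np.asarray(getattr(baseline_probs, "probabilities", baseline_probs), dtype=np.float64)
    if probs.ndim == 3:
        probs = probs[..., 1]
    if probs.shape != label.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs label {label.shape}")
    hot = probs >= prob_threshold
    if not hot.any():
        return PenaltyRegionMask.empty(label.shape)
    # distance from each pixel to the nearest mark pixel
    if label.values.any():
        dist = ndimage.distance_transform_edt(label.values == 0)
        hot &= dist > exclusion_radius
    return PenaltyRegionMask(hot)


def build_weight_mask(
    label: LabelMask,
    penalty: PenaltyRegionMask,
    penalty_weight: float,
    halo_radius: float = 10.0,
) -> WeightMask:
    """Assemble the per-pixel loss weights p_n.

    Weight 0 on the halo ring (within ``halo_radius`` of a mark disk but not
    in it), ``penalty_weight`` on penalty pixels, 1 elsewhere.  Where halo and
    penalty overlap the halo wins (weight 0), so penalties never abut the
    annotated points.
    """
    if penalty_weight < 0:
        raise ValueError("penalty_weight must be non-negative")
    if penalty.shape != label.shape:
        raise ValueError(f"shape mismatch: penalty {penalty.shape} vs label {label.shape}")
    w = np.ones(label.shape, dtype=np.float64)
    w[penalty.values] = penalty_weight
    halo = halo_ring(label, halo_radius)
    w[halo] = 0.0
    return WeightMask(w, penalty_weight=penalty_weight, halo_radius=halo_radius)


def halo_ring(label: LabelMask, halo_radius: float) -> np.ndarray:
    """Boolean mask of the non-punishing ring around the mark disks."""
    if halo_radius <= 0 or not label.values.any():
        return np.zeros(label.shape, dtype=bool)
    dist = ndimage.distance_transform_edt(label.values == 0)
    return (dist > 0) & (dist <= halo_radius)


# ---------------------------------------------------------------------------
# file formats


def read_annotation_csv(path, mark_diameter: float, image_shape: tuple[int, int]):
    """Read a ``image_id,row,col`` CSV into per-image :class:`PointAnnotation`.

    Returns a dict mapping image id to annotation.  Images listed with no
    rows (NaN coordinates) yield empty annotations.
    """
    df = pd.read_csv(path)
    expected = {"image_id", "row", "col"}
    if not expected.issubset(df.columns):
        raise ValueError(f"annotation CSV needs columns {sorted(expected)}")
    out: dict[str, PointAnnotation] = {}
    for image_id, group in df.groupby("image_id", sort=False):
        pts = group[["row", "col"]].dropna().to_numpy(dtype=float)
        out[str(image_id)] = PointAnnotation(
            points=tuple(map(tuple, pts)),
            mark_diameter=mark_diameter,
            image_shape=image_shape,
        )
    return out


def write_annotation_csv(path, annotations: dict[str, PointAnnotation]) -> None:
    rows = [
        {"image_id": image_id, "row": r, "col": c}
        for image_id, ann in annotations.items()
        for r, c in ann.points
    ]
    pd.DataFrame(rows, columns=["image_id", "row", "col"]).to_csv(path, index=False)


def encode_mask(
    label: LabelMask,
    penalty: PenaltyRegionMask | None = None,
    halo_radius: float | None = None,
) -> np.ndarray:
    """Single-channel encoding 0=background, 1=PSEP, 2=penalty; passing a
    ``halo_radius`` adds the halo ring as 3 (extended debug encoding)."""
    out = label.values.astype(np.uint8).copy()
    if penalty is not None:
        out[penalty.values & (out == 0)] = PENALTY
    if halo_radius is not None:
        out[halo_ring(label, halo_radius) & (out == 0)] = HALO
    return out


def write_mask_png(path, encoded: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(encoded, dtype=np.uint8))


def read_mask_png(path) -> tuple[LabelMask, PenaltyRegionMask]:
    enc = np.asarray(iio.imread(path))
    if enc.ndim == 3:
        enc = enc[..., 0]
    return LabelMask((enc == PSEP).astype(np.uint8)), PenaltyRegionMask(enc == PENALTY)
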