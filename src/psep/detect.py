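"""From per-pixel PSEP probabilities to discrete detection points.

The probability map is thresholded on the PSEP softmax channel, and each
8-connected component of the resulting binary map yields one detection at
the unweighted centroid of its pixels (annotation marks are filled disks, so
the disk center is the intended location).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class BinaryMap:
    """Thresholded PSEP-probability map."""

    values: np.ndarray
    threshold: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=bool))


@dataclass(frozen=True)
class DetectionSet:
    """One point per connected component, with the component pixel counts."""

    points: tuple[tuple[float, float], ...]
    component_sizes: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "points", tuple((float(r), float(c)) for r, c in self.points))
        object.__setattr__(self, "component_sizes", tuple(int(s) for s in self.component_sizes))

    def __len__(self) -> int:
        return len(self.points)


def threshold_softmax(probs, threshold: float) -> BinaryMap:
    """Binarize the PSEP channel at ``threshold`` (exclusive of 0 and 1)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly between 0 and 1")
    p = np.asarray(getattr(probs, "probabilities", probs), dtype=np.float64)
    if p.ndim == 3:
        p = p[..., 1]
    return BinaryMap(p >= threshold, threshold)


def extract_points(bmap: BinaryMap, min_area: int = 1) -> DetectionSet:
    """Centroid of every 8-connected component of at least ``min_area`` px."""
    labels, n = ndimage.label(bmap.values, structure=_EIGHT)
    if n == 0:
        return DetectionSet(())
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, idx).astype(int)
    centroids = ndimage.center_of_mass(bmap.values, labels, idx)
    keep = sizes >= min_area
    return DetectionSet(
        tuple(c for c, k in zip(centroids, keep) if k),
        tuple(sizes[keep]),
    )


def detect(probs, threshold: float = 0.4, min_area: int = 1) -> DetectionSet:
    """Threshold then extract, in one call (default operating point 0.4)."""
    return extract_points(threshold_softmax(probs, threshold), min_area=min_area)
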