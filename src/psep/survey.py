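"""Range classification of per-image counts, stratified sampling and maps.

For survey purposes per-image PSEP counts are binned into ``2 * n_steps + 1``
ranges around the across-field average count: Range 0 holds exactly the
empty images, Range i (i >= 1) the counts in ``((i-1) * b, i * b]`` with
bandwidth ``b = average / n_steps``, and the top range is open above.  With
the typical average of 60 and five steps up and down this gives eleven
ranges of bandwidth 12 (Range 5 = 48 < count <= 60, Range 10 = count > 108).

The ranges drive stratified evaluation sampling (one random image per field
per range), per-range metric summaries, count histograms and geo-referenced
field maps of predicted counts.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RangeScheme:
    """Count-bin definition built from an average count and step number."""

    average_count: float
    n_steps: int

    def __post_init__(self):
        if self.average_count <= 0:
            raise ValueError("average_count must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")

    @property
    def bandwidth(self) -> float:
        return self.average_count / self.n_steps

    @property
    def n_ranges(self) -> int:
        return 2 * self.n_steps + 1

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(range(self.n_ranges))

    def bounds(self, label: int) -> tuple[float, float]:
        """(low, high] bounds of a range; Range 0 is {0}, the top range has
        high = inf."""
        if not 0 <= label < self.n_ranges:
            raise ValueError(f"label {label} outside 0..{self.n_ranges - 1}")
        if label == 0:
            return (0.0, 0.0)
        high = math.inf if label == self.n_ranges - 1 else label * self.bandwidth
        return ((label - 1) * self.bandwidth, high)

    def describe(self) -> list[str]:
        """Human-readable range list (mirrors the survey-figure captions)."""
        out = [f"Range 0 (PSEPs = 0)"]
        for i in range(1, self.n_ranges - 1):
            lo, hi = self.bounds(i)
            out.append(f"Range {i} ({lo:g} < PSEPs ≤ {hi:g})")
        lo, _ = self.bounds(self.n_ranges - 1)
        out.append(f"Range {self.n_ranges - 1} ({lo:g} < PSEPs)")
        return out


@dataclass(frozen=True)
class FieldRecord:
    """Per-image survey record: position, predicted count and its range."""

    image_id: str
    position: tuple[float, float] | None  # (lat, lon) degrees
    predicted_count: int
    range_label: int


def build_range_scheme(average_count: float, n_steps: int = 5) -> RangeScheme:
    """Ranges of bandwidth ``average_count / n_steps``: ``n_steps`` up and
    down from the average plus the singleton zero range."""
    return RangeScheme(float(average_count), int(n_steps))


def classify_range(count: int, scheme: RangeScheme) -> int:
    """Range label of a count; intervals are (low, high], upper inclusive."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return 0
    label = math.ceil(count / scheme.bandwidth - 1e-12)
    return min(label, scheme.n_ranges - 1)


def make_field_records(
    counts: dict[str, int],
    scheme: RangeScheme,
    positions: dict[str, tuple[float, float]] | None = None,
) -> list[FieldRecord]:
    positions = positions or {}
    return [
        FieldRecord(image_id, positions.get(image_id), int(c), classify_range(int(c), scheme))
        for image_id, c in counts.items()
    ]


def stratified_select(
    records_by_field: dict[str, Sequence[FieldRecord]],
    scheme: RangeScheme,
    per_cell: int = 1,
    seed: int = 0,
) -> list[str]:
    """Random image ids, up to ``per_cell`` per (field, range) cell.

    With three fields and all eleven ranges occupied at ``per_cell=1`` this
    yields the 33-image evaluation set of the standard survey protocol.
    Empty cells contribute nothing.
    """
    if per_cell < 1:
        raise ValueError("per_cell must be at least 1")
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for field_name in records_by_field:
        records = list(records_by_field[field_name])
        for label in scheme.labels:
            cell = [r.image_id for r in records if r.range_label == label]
            if not cell:
                continue
            take = min(per_cell, len(cell))
            picks = rng.choice(len(cell), size=take, replace=False)
            selected.extend(cell[i] for i in sorted(picks))
    return selected


# ---------------------------------------------------------------------------
# augmentation


def augment_scene(image: np.ndarray, points: Sequence[tuple[float, float]]):
    """Four deterministic variants of a scene: identity, 90-degree rotation,
    transpose, and the transpose of the rotation (a left-right flip).
    Point coordinates are transformed consistently with the pixels."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    pts = [(float(r), float(c)) for r, c in points]
    rot = np.rot90(img)  # (r, c) -> (w-1-c, r), shape (W, H)
    variants = [
        ("orig", img, pts),
        ("rot90", rot, [(w - 1 - c, r) for r, c in pts]),
        ("transpose", img.swapaxes(0, 1), [(c, r) for r, c in pts]),
        ("rot90_transpose", rot.swapaxes(0, 1), [(r, w - 1 - c) for r, c in pts]),
    ]
    return variants


def augment_set(items: Sequence[tuple]) -> list[tuple]:
    """Apply :func:`augment_scene` to (image, points) pairs; n in, 4n out
    (212 annotated images become the 848-image training set)."""
    out = []
    for image, points in items:
        pts = getattr(points, "points", points)
        out.extend((img, p, name) for name, img, p in augment_scene(image, pts))
    return out


# ---------------------------------------------------------------------------
# survey outputs


_PALETTE = [
    "#4d4d4d", "#2166ac", "#4393c3", "#92c5de", "#d1e5f0", "#fddbc7",
    "#f4a582", "#d6604d", "#b2182b", "#762a83", "#1b7837",
]


def range_color(label: int) -> str:
    return _PALETTE[label % len(_PALETTE)]


def count_histogram(counts: Sequence[int], scheme: RangeScheme) -> pd.DataFrame:
    """Images per range (the survey's count-distribution histogram)."""
    labels = [classify_range(int(c), scheme) for c in counts]
    freq = {lab: 0 for lab in scheme.labels}
    for lab in labels:
        freq[lab] += 1
    return pd.DataFrame(
        {"range": list(freq), "n_images": list(freq.values())}
    )


def records_to_frame(records: Sequence[FieldRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "lat": None if r.position is None else r.position[0],
                "lon": None if r.position is None else r.position[1],
                "predicted_count": r.predicted_count,
                "range_label": r.range_label,
            }
            for r in records
        ],
        columns=["image_id", "lat", "lon", "predicted_count", "range_label"],
    )


def field_map_geojson(records: Sequence[FieldRecord]) -> dict:
    """GeoJSON FeatureCollection of per-image points keyed by range."""
    features = []
    for r in records:
        if r.position is None:
            warnings.warn(f"record {r.image_id} has no position; skipped", stacklevel=2)
            continue
        lat, lon = r.position
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [lon, lat]},
                "properties": {
                    "image_id": r.image_id,
                    "predicted_count": r.predicted_count,
                    "range": r.range_label,
                    "color": range_color(r.range_label),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def render_field_map(
    records: Sequence[FieldRecord],
    scheme: RangeScheme,
    png_path=None,
    geojson_path=None,
) -> dict:
    """Write the geo-referenced predicted-count map.

    One colored marker per image position, color keyed by range label with a
    deterministic palette.  Returns the GeoJSON dict; optionally writes it
    and a rendered PNG.
    """
    geo = field_map_geojson(records)
    if geojson_path is not None:
        with open(geojson_path, "w") as fh:
            json.dump(geo, fh, indent=2)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        for feat in geo["features"]:
            lon, lat = feat["geometry"]["coordinates"]
            ax.plot(lon, lat, "o", color=feat["properties"]["color"], ms=6)
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        ax.set_title("Predicted PSEP count ranges")
        handles = [
            plt.Line2D([], [], marker="o", ls="", color=range_color(lab), label=f"Range {lab}")
            for lab in scheme.labels
        ]
        ax.legend(handles=handles, fontsize=6, loc="center left", bbox_to_anchor=(1, 0.5))
        fig.savefig(png_path, bbox_inches="tight", dpi=120)
        plt.close(fig)
    return geo
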