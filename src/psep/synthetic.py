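"""Synthetic top-view field scenes with known emergence points.

Real training data for PSEP detection is top-view imagery of cereal fields
sown by seed drills: textured soil, plants at all densities whose narrow
leaves radiate from the stem base, and plenty of things that *look like*
stem bases -- tips of leaves, weeds and plant residue -- which are exactly
what a penalty-free model tends to fire on.  This module renders such
scenes procedurally so the whole pipeline can be exercised with exact
ground truth:

* background: soil tone with low-frequency blotches, fine grain and
  speckle clutter;
* plants: 2-4 elongated, curved leaves radiating from a base point that is
  darkened into a small convergence blob; the base pixel is the
  ground-truth PSEP;
* distractors: lone leaf strokes, near-touching leaf-tip pairs and pale
  residue strokes with *no* associated truth point.

Scenes are deterministic functions of their spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .annotations import PointAnnotation, write_annotation_csv


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    image_shape: tuple[int, int] = (128, 128)
    plant_count: int = 20
    distractor_rate: float = 0.0  # distractors per plant
    plant_scale: tuple[float, float] = (5.0, 9.0)  # leaf length range, px
    row_structure: tuple[float, float] | None = None  # (row spacing, jitter) px
    soil_rgb: tuple[float, float, float] = (0.42, 0.33, 0.24)
    soil_noise: float = 0.05
    clutter_density: float = 0.0008  # speckles per pixel
    leaf_rgb: tuple[float, float, float] = (0.20, 0.52, 0.16)
    min_separation: float = 0.0  # blue-noise spacing between plant bases
    margin: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.plant_count < 0 or self.distractor_rate < 0:
            raise ValueError("counts and rates must be non-negative")


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) float in [0, 1]
    truth: PointAnnotation
    distractor_points: tuple[tuple[float, float], ...] = ()

    @property
    def plant_count(self) -> int:
        return len(self.truth)


def easy_spec(plant_count: int, image_shape=(256, 256), seed: int = 0) -> SceneSpec:
    """High-contrast, well-separated plants, no distractors: the preset a
    briefly trained small model should handle almost perfectly."""
    return SceneSpec(
        image_shape=image_shape,
        plant_count=plant_count,
        distractor_rate=0.0,
        plant_scale=(5.0, 8.0),
        soil_noise=0.04,
        clutter_density=0.0004,
        leaf_rgb=(0.18, 0.58, 0.14),
        min_separation=13.0,
        seed=seed,
    )


def hard_spec(plant_count: int, image_shape=(128, 128), seed: int = 0) -> SceneSpec:
    """Seed-drill-like rows with jitter and overlap plus leaf-tip / residue
    distractors: the preset that provokes false positives at distractor
    sites in penalty-free training."""
    return SceneSpec(
        image_shape=image_shape,
        plant_count=plant_count,
        distractor_rate=2.5,
        plant_scale=(5.0, 9.0),
        row_structure=(26.0, 2.5),
        soil_noise=0.06,
        clutter_density=0.001,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# drawing primitives


def _stamp_disk(cover: np.ndarray, r: float, c: float, radius: float) -> None:
    """Accumulate anti-aliased disk coverage into ``cover`` (max blend)."""
    h, w = cover.shape
    r0, r1 = max(0, int(r - radius - 1)), min(h - 1, int(r + radius + 1))
    c0, c1 = max(0, int(c - radius - 1)), min(w - 1, int(c + radius + 1))
    if r0 > r1 or c0 > c1:
        return
    rows = np.arange(r0, r1 + 1)[:, None]
    cols = np.arange(c0, c1 + 1)[None, :]
    dist = np.hypot(rows - r, cols - c)
    a = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    np.maximum(cover[r0 : r1 + 1, c0 : c1 + 1], a, out=cover[r0 : r1 + 1, c0 : c1 + 1])


def _stroke(
    img: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    ctrl: tuple[float, float],
    width0: float,
    width1: float,
    color: np.ndarray,
) -> None:
    """Paint a tapered quadratic-Bezier stroke from p0 (width0) to p1."""
    length = np.hypot(p1[0] - p0[0], p1[1] - p0[1]) + 1.0
    ts = np.linspace(0.0, 1.0, max(int(3 * length), 4))
    cover = np.zeros(img.shape[:2], dtype=np.float32)
    for t in ts:
        r = (1 - t) ** 2 * p0[0] + 2 * (1 - t) * t * ctrl[0] + t**2 * p1[0]
        c = (1 - t) ** 2 * p0[1] + 2 * (1 - t) * t * ctrl[1] + t**2 * p1[1]
        _stamp_disk(cover, r, c, width0 + (width1 - width0) * t)
    img += cover[..., None] * (color[None, None, :] - img)


def _leaf(rng, img, base, angle, length, color):
    """One curved leaf from ``base`` outward; returns the tip point."""
    d = np.array([np.sin(angle), np.cos(angle)])
    perp = np.array([-d[1], d[0]])
    bend = rng.normal(0.0, 0.22) * length
    tip = np.asarray(base) + d * length + perp * rng.normal(0.0, 0.1) * length
    ctrl = np.asarray(base) + d * length * 0.5 + perp * bend
    _stroke(img, tuple(base), tuple(tip), tuple(ctrl), 1.4, 0.6, color)
    return tuple(tip)


def _draw_plant(rng, img, base, spec: SceneSpec) -> None:
    n_leaves = int(rng.integers(2, 5))
    base_color = np.clip(np.asarray(spec.leaf_rgb) * 0.6, 0, 1)
    angles = rng.uniform(0, 2 * np.pi) + np.linspace(0, 2 * np.pi, n_leaves, endpoint=False)
    angles = angles + rng.normal(0, 0.35, n_leaves)
    for a in angles:
        length = rng.uniform(*spec.plant_scale)
        shade = np.clip(np.asarray(spec.leaf_rgb) + rng.normal(0, 0.04, 3), 0, 1)
        _leaf(rng, img, base, a, length, shade)
    # darker convergence blob marks the stem base
    cover = np.zeros(img.shape[:2], dtype=np.float32)
    _stamp_disk(cover, base[0], base[1], rng.uniform(1.3, 1.8))
    img += cover[..., None] * (base_color[None, None, :] - img)


def _draw_distractor(rng, img, spec: SceneSpec) -> tuple[float, float]:
    """One PSEP lookalike with no truth point; returns its site."""
    h, w = spec.image_shape
    m = spec.margin
    site = (rng.uniform(m, h - m), rng.uniform(m, w - m))
    kind = rng.choice(["vee", "tip", "residue"], p=[0.4, 0.4, 0.2])
    if kind == "vee":
        # tips of two neighbouring leaves converging on the site: a local
        # green convergence like a stem base, but the thin tip ends stop
        # just short of meeting and there is no dark basal blob
        a0 = rng.uniform(0, 2 * np.pi)
        for a in (a0, a0 + rng.uniform(1.8, np.pi)):
            d = np.array([np.sin(a), np.cos(a)])
            gap = rng.uniform(0.2, 0.8)
            length = rng.uniform(*spec.plant_scale) * 0.8
            tip = np.asarray(site) + d * gap
            outer = np.asarray(site) + d * (gap + length)
            perp = np.array([-d[1], d[0]])
            ctrl = (tip + outer) / 2 + perp * rng.normal(0.0, 0.18) * length
            shade = np.clip(np.asarray(spec.leaf_rgb) + rng.normal(0, 0.04, 3), 0, 1)
            _stroke(img, tuple(outer), tuple(tip), tuple(ctrl), 1.4, 0.6, shade)
    elif kind == "tip":
        a = rng.uniform(0, 2 * np.pi)
        shade = np.clip(np.asarray(spec.leaf_rgb) + rng.normal(0, 0.05, 3), 0, 1)
        _leaf(rng, img, site, a, rng.uniform(*spec.plant_scale), shade)
    else:
        # pale residue straw
        a = rng.uniform(0, 2 * np.pi)
        d = np.array([np.sin(a), np.cos(a)])
        length = rng.uniform(*spec.plant_scale) * 1.2
        p1 = np.asarray(site) + d * length
        ctrl = np.asarray(site) + d * length * 0.5
        pale = np.clip(np.asarray(spec.soil_rgb) * np.array([1.6, 1.5, 1.2]), 0, 1)
        _stroke(img, site, tuple(p1), tuple(ctrl), 0.9, 0.9, pale)
    return site


def _background(rng, spec: SceneSpec) -> np.ndarray:
    h, w = spec.image_shape
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = spec.soil_rgb
    blotch = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=9)
    blotch = blotch / (np.abs(blotch).max() + 1e-9)
    img *= (1 + 0.18 * blotch)[..., None]
    img += rng.normal(0, spec.soil_noise, (h, w, 1))
    n_speckles = int(spec.clutter_density * h * w)
    for _ in range(n_speckles):
        r, c = rng.uniform(0, h), rng.uniform(0, w)
        tone = rng.uniform(0.5, 1.7)
        color = np.clip(np.asarray(spec.soil_rgb) * tone, 0, 1)
        cover = np.zeros((h, w), dtype=np.float32)
        _stamp_disk(cover, r, c, rng.uniform(0.6, 1.4))
        img += cover[..., None] * (color[None, None, :] - img)
    return np.clip(img, 0, 1)


def _place_bases(rng, spec: SceneSpec) -> list[tuple[float, float]]:
    h, w = spec.image_shape
    m = spec.margin
    if h <= 2 * m or w <= 2 * m:
        raise ValueError("image too small for the sprite margin")
    bases: list[tuple[float, float]] = []
    if spec.row_structure is not None:
        spacing, jitter = spec.row_structure
        row_lines = np.arange(spacing / 2, h - m, spacing)
        for _ in range(spec.plant_count):
            line = row_lines[int(rng.integers(0, len(row_lines)))]
            r = float(np.clip(line + rng.normal(0, jitter), m, h - 1 - m))
            bases.append((r, float(rng.uniform(m, w - 1 - m))))
        return bases
    for _ in range(spec.plant_count):
        for _attempt in range(200):
            cand = (float(rng.uniform(m, h - 1 - m)), float(rng.uniform(m, w - 1 - m)))
            if spec.min_separation <= 0 or all(
                np.hypot(cand[0] - b[0], cand[1] - b[1]) >= spec.min_separation for b in bases
            ):
                bases.append(cand)
                break
        else:
            raise ValueError(
                f"could not place {spec.plant_count} plants with "
                f"min_separation={spec.min_separation} in {spec.image_shape}"
            )
    return bases


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one scene; pixel-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    img = _background(rng, spec)
    bases = _place_bases(rng, spec)
    for base in bases:
        _draw_plant(rng, img, base, spec)
    n_distractors = int(round(spec.distractor_rate * spec.plant_count))
    sites = tuple(_draw_distractor(rng, img, spec) for _ in range(n_distractors))
    truth = PointAnnotation(
        points=tuple(bases), mark_diameter=20.0, image_shape=spec.image_shape
    )
    return SyntheticScene(np.clip(img, 0, 1), truth, sites)


def generate_dataset(specs, out_dir=None, mark_diameter: float = 20.0):
    """Render a list of specs; optionally write PNGs plus the annotation CSV
    dialect consumed by the mask builder (columns image_id,row,col)."""
    scenes = [generate_scene(s) for s in specs]
    annotations = {
        f"scene_{i:04d}": replace_diameter(s.truth, mark_diameter)
        for i, s in enumerate(scenes)
    }
    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, scene in enumerate(scenes):
            iio.imwrite(
                out / f"scene_{i:04d}.png", (scene.image * 255).astype(np.uint8)
            )
        write_annotation_csv(out / "annotations.csv", annotations)
    return scenes, annotations


def replace_diameter(ann: PointAnnotation, mark_diameter: float) -> PointAnnotation:
    return PointAnnotation(ann.points, mark_diameter, ann.image_shape)


def range_covering_counts(scheme) -> list[int]:
    """One plant count inside each range of a scheme (range midpoint-ish);
    for the average-60 scheme: 0, 6, 18, ..., 114."""
    counts = [0]
    b = scheme.bandwidth
    for i in range(1, scheme.n_ranges):
        counts.append(int(round((i - 0.5) * b)))
    return counts


# ---------------------------------------------------------------------------
# spec (de)serialization


def specs_to_yaml(specs, path) -> None:
    data = []
    for s in specs:
        d = {
            "image_shape": list(s.image_shape),
            "plant_count": s.plant_count,
            "distractor_rate": s.distractor_rate,
            "plant_scale": list(s.plant_scale),
            "row_structure": None if s.row_structure is None else list(s.row_structure),
            "soil_rgb": list(s.soil_rgb),
            "soil_noise": s.soil_noise,
            "clutter_density": s.clutter_density,
            "leaf_rgb": list(s.leaf_rgb),
            "min_separation": s.min_separation,
            "margin": s.margin,
            "seed": s.seed,
        }
        data.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def specs_from_yaml(path) -> list[SceneSpec]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    specs = []
    for d in data:
        for key in ("image_shape", "plant_scale", "soil_rgb", "leaf_rgb", "row_structure"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        specs.append(SceneSpec(**d))
    return specs
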