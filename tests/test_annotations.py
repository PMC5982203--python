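"""Mask construction: disk rasterization, overlay parsing, penalty regions,
weight masks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psep.annotations import (
    LabelMask,
    PenaltyRegionMask,
    PointAnnotation,
    build_weight_mask,
    derive_penalty_regions,
    encode_mask,
    halo_ring,
    parse_overlay_layer,
    rasterize_marks,
    read_annotation_csv,
    read_mask_png,
    write_annotation_csv,
    write_mask_png,
)

import oracles


class TestRasterizeMarks:
    def test_empty_annotation_gives_zero_mask(self):
        ann = PointAnnotation((), mark_diameter=20, image_shape=(100, 100))
        assert rasterize_marks(ann).values.sum() == 0

    def test_disk_membership_by_euclidean_distance(self):
        ann = PointAnnotation([(50, 50)], mark_diameter=20, image_shape=(100, 100))
        mask = rasterize_marks(ann).values
        assert mask[50, 50] == 1
        assert mask[50, 60] == 1  # distance 10 == radius, boundary inclusive
        assert mask[50, 65] == 0  # distance 15 > 10

    def test_pixel_count_matches_brute_force(self):
        ann = PointAnnotation([(41, 57)], mark_diameter=20, image_shape=(100, 100))
        expected = oracles.disk_pixel_count((41, 57), 10.0, (100, 100))
        assert rasterize_marks(ann).values.sum() == expected

    def test_overlapping_disks_merge(self):
        one = rasterize_marks(PointAnnotation([(50, 50)], 20, (100, 100))).values
        two = rasterize_marks(PointAnnotation([(50, 50), (50, 52)], 20, (100, 100))).values
        assert two.sum() < 2 * one.sum()
        assert np.all(two >= one)

    def test_out_of_bounds_point_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            PointAnnotation([(100, 50)], 20, (100, 100))

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.tuples(st.integers(5, 58), st.integers(5, 58)), min_size=0, max_size=5
        )
    )
    def test_point_order_invariance_and_idempotence(self, pts):
        a = rasterize_marks(PointAnnotation(pts, 8, (64, 64))).values
        b = rasterize_marks(PointAnnotation(list(reversed(pts)), 8, (64, 64))).values
        assert np.array_equal(a, b)
        again = rasterize_marks(PointAnnotation(pts, 8, (64, 64))).values
        assert np.array_equal(a, again)


class TestOverlayParsing:
    @staticmethod
    def _overlay_with_disks(points, shape=(64, 64), diameter=10):
        mask = rasterize_marks(PointAnnotation(points, diameter, shape)).values
        img = np.zeros(shape + (4,), dtype=np.uint8)
        img[mask == 1] = (255, 0, 0, 255)
        return img

    def test_blank_overlay_yields_no_points(self):
        ann = parse_overlay_layer(np.zeros((32, 32, 4), dtype=np.uint8))
        assert len(ann) == 0

    def test_disk_centroid_recovers_center(self):
        img = self._overlay_with_disks([(30, 40)])
        ann = parse_overlay_layer(img, mark_diameter=10)
        assert len(ann) == 1
        r, c = ann.points[0]
        assert abs(r - 30) <= 0.5 and abs(c - 40) <= 0.5

    def test_two_disjoint_disks_two_points(self):
        img = self._overlay_with_disks([(15, 15), (45, 45)])
        assert len(parse_overlay_layer(img)) == 2

    def test_non_disk_component_warns_but_returns_centroid(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        img[20, 5:35] = (255, 0, 0)  # a line, eccentricity ~1
        with pytest.warns(UserWarning, match="disk"):
            ann = parse_overlay_layer(img)
        assert len(ann) == 1

    def test_red_tolerance_excludes_other_colors(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[10:14, 10:14] = (0, 255, 0)
        assert len(parse_overlay_layer(img)) == 0


class TestPenaltyRegions:
    def _label(self, points=((32, 32),), shape=(64, 64), diameter=10):
        return rasterize_marks(PointAnnotation(points, diameter, shape))

    def test_true_positive_response_is_subtracted(self):
        label = self._label()
        probs = np.zeros((64, 64))
        probs[label.values == 1] = 0.9  # fires only inside the mark
        pen = derive_penalty_regions(probs, label, exclusion_radius=10, prob_threshold=0.5)
        assert not pen.values.any()

    def test_far_false_positive_blob_is_penalized(self):
        label = self._label(points=((5, 5),), diameter=4)
        probs = np.zeros((64, 64))
        probs[50:55, 50:55] = 0.8  # ~63 px from the mark
        pen = derive_penalty_regions(probs, label, exclusion_radius=10, prob_threshold=0.5)
        assert pen.values[50:55, 50:55].all()
        assert pen.values.sum() == 25

    def test_all_zero_probabilities_give_empty_mask(self):
        pen = derive_penalty_regions(np.zeros((64, 64)), self._label(), 10, 0.5)
        assert not pen.values.any()

    def test_subthreshold_probabilities_give_empty_mask(self):
        probs = np.full((64, 64), 0.49)
        pen = derive_penalty_regions(probs, self._label(), 10, 0.5)
        assert not pen.values.any()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            derive_penalty_regions(np.zeros((32, 32)), self._label(), 10, 0.5)


class TestWeightMask:
    def _fixture(self):
        label = rasterize_marks(PointAnnotation([(32, 32)], 10, (64, 64)))
        pen = np.zeros((64, 64), dtype=bool)
        pen[5:8, 5:8] = True  # 9-px blob far from the mark
        return label, PenaltyRegionMask(pen)

    def test_three_weight_levels(self):
        label, pen = self._fixture()
        w = build_weight_mask(label, pen, penalty_weight=75, halo_radius=5)
        assert set(np.unique(w.values)) == {0.0, 1.0, 75.0}
        assert (w.values == 75).sum() == 9

    def test_zero_weight_exactly_on_halo_ring(self):
        label, pen = self._fixture()
        w = build_weight_mask(label, pen, penalty_weight=50, halo_radius=5)
        ring = halo_ring(label, 5)
        assert np.array_equal(w.values == 0, ring)
        # mark disk itself keeps weight 1
        assert (w.values[label.values == 1] == 1).all()

    def test_penalty_weight_zero_two_levels(self):
        label, pen = self._fixture()
        w = build_weight_mask(label, pen, penalty_weight=0, halo_radius=5)
        assert set(np.unique(w.values)) <= {0.0, 1.0}

    def test_no_marks_no_penalty_all_ones(self):
        label = LabelMask(np.zeros((32, 32), dtype=np.uint8))
        w = build_weight_mask(label, PenaltyRegionMask.empty((32, 32)), 50, 5)
        assert (w.values == 1).all()

    def test_halo_precedence_over_penalty(self):
        label = rasterize_marks(PointAnnotation([(32, 32)], 10, (64, 64)))
        pen = np.zeros((64, 64), dtype=bool)
        pen[32, 38:42] = True  # inside the halo ring (radius 5..10 from center)
        w = build_weight_mask(label, PenaltyRegionMask(pen), 50, halo_radius=5)
        assert (w.values[32, 39:41] == 0).all()

    def test_negative_penalty_weight_rejected(self):
        label, pen = self._fixture()
        with pytest.raises(ValueError):
            build_weight_mask(label, pen, penalty_weight=-1, halo_radius=5)

    def test_penalty_halo_and_disk_pixels_disjoint(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pts = [(rng.integers(10, 54), rng.integers(10, 54)) for _ in range(3)]
            label = rasterize_marks(PointAnnotation(pts, 8, (64, 64)))
            probs = rng.uniform(0, 1, (64, 64))
            pen = derive_penalty_regions(probs, label, exclusion_radius=8, prob_threshold=0.7)
            ring = halo_ring(label, 4)
            disk = label.values == 1
            assert not (pen.values & disk).any()
            assert not (pen.values & ring).any()
            assert not (ring & disk).any()


class TestFileFormats:
    def test_mask_png_roundtrip(self, tmp_path):
        label = rasterize_marks(PointAnnotation([(20, 20)], 10, (48, 48)))
        pen = np.zeros((48, 48), dtype=bool)
        pen[40:44, 40:44] = True
        enc = encode_mask(label, PenaltyRegionMask(pen), halo_radius=4)
        assert set(np.unique(enc)) == {0, 1, 2, 3}
        path = tmp_path / "mask.png"
        write_mask_png(path, enc)
        label2, pen2 = read_mask_png(path)
        assert np.array_equal(label2.values, label.values)
        assert np.array_equal(pen2.values, pen)

    def test_annotation_csv_roundtrip(self, tmp_path):
        anns = {
            "img_a": PointAnnotation([(10, 11), (20, 21)], 6, (64, 64)),
            "img_b": PointAnnotation([(5.5, 7.25)], 6, (64, 64)),
        }
        path = tmp_path / "ann.csv"
        write_annotation_csv(path, anns)
        back = read_annotation_csv(path, mark_diameter=6, image_shape=(64, 64))
        assert back["img_a"].points == anns["img_a"].points
        assert back["img_b"].points == anns["img_b"].points
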