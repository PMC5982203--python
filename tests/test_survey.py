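"""Range scheme, count classification, stratified sampling, augmentation
and survey outputs."""

import json

import numpy as np
import pytest

from psep.survey import (
    FieldRecord,
    augment_scene,
    augment_set,
    build_range_scheme,
    classify_range,
    count_histogram,
    field_map_geojson,
    make_field_records,
    records_to_frame,
    render_field_map,
    stratified_select,
)


class TestRangeScheme:
    def test_average_60_five_steps(self):
        scheme = build_range_scheme(60, 5)
        assert scheme.bandwidth == 12
        assert scheme.n_ranges == 11

    def test_minimal_scheme(self):
        scheme = build_range_scheme(10, 1)
        assert scheme.n_ranges == 3
        assert scheme.bounds(0) == (0, 0)
        assert scheme.bounds(1) == (0, 10)
        assert scheme.bounds(2) == (10, np.inf)

    def test_average_60_boundaries_enumerated(self):
        """The full average-60 range list: Range 0 = {0}, Range i =
        (12(i-1), 12i], Range 10 open above."""
        scheme = build_range_scheme(60, 5)
        assert scheme.bounds(1) == (0, 12)
        assert scheme.bounds(2) == (12, 24)
        assert scheme.bounds(3) == (24, 36)
        assert scheme.bounds(4) == (36, 48)
        assert scheme.bounds(5) == (48, 60)
        assert scheme.bounds(6) == (60, 72)
        assert scheme.bounds(7) == (72, 84)
        assert scheme.bounds(8) == (84, 96)
        assert scheme.bounds(9) == (96, 108)
        assert scheme.bounds(10) == (108, np.inf)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_range_scheme(0, 5)
        with pytest.raises(ValueError):
            build_range_scheme(60, 0)


class TestClassifyRange:
    @pytest.mark.parametrize(
        "count,label",
        [(55, 5), (0, 0), (200, 10), (48, 4), (49, 5), (12, 1), (1, 1), (108, 9), (109, 10)],
    )
    def test_average_60_examples(self, count, label):
        scheme = build_range_scheme(60, 5)
        assert classify_range(count, scheme) == label

    def test_partition_of_nonnegative_integers(self):
        """Every count 0..500 gets exactly one label consistent with its
        range bounds."""
        scheme = build_range_scheme(60, 5)
        for count in range(501):
            label = classify_range(count, scheme)
            lo, hi = scheme.bounds(label)
            if label == 0:
                assert count == 0
            else:
                assert lo < count <= hi

    def test_fractional_bandwidth(self):
        scheme = build_range_scheme(50, 4)  # bandwidth 12.5
        assert classify_range(12, scheme) == 1
        assert classify_range(13, scheme) == 2

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_range(-1, build_range_scheme(60, 5))


def _records(field_counts, scheme):
    return {
        field_name: [
            FieldRecord(f"{field_name}_{i}", None, c, classify_range(c, scheme))
            for i, c in enumerate(counts)
        ]
        for field_name, counts in field_counts.items()
    }


class TestStratifiedSelect:
    def test_three_fields_eleven_ranges_yield_33(self):
        scheme = build_range_scheme(60, 5)
        counts = [0, 6, 18, 30, 42, 54, 66, 78, 90, 102, 114] * 2  # all ranges twice
        recs = _records({"f1": counts, "f2": counts, "f3": counts}, scheme)
        assert len(stratified_select(recs, scheme, per_cell=1, seed=0)) == 33

    def test_single_occupied_cell(self):
        scheme = build_range_scheme(60, 5)
        recs = _records({"f1": [55]}, scheme)
        assert len(stratified_select(recs, scheme, per_cell=1, seed=0)) == 1

    def test_same_seed_same_selection(self):
        scheme = build_range_scheme(60, 5)
        rng = np.random.default_rng(0)
        recs = _records({"f1": rng.integers(0, 120, 50).tolist()}, scheme)
        a = stratified_select(recs, scheme, seed=42)
        b = stratified_select(recs, scheme, seed=42)
        assert a == b

    def test_at_most_one_per_cell(self):
        scheme = build_range_scheme(60, 5)
        rng = np.random.default_rng(1)
        recs = _records({"f1": rng.integers(0, 120, 80).tolist()}, scheme)
        chosen = stratified_select(recs, scheme, per_cell=1, seed=3)
        by_id = {r.image_id: r.range_label for r in recs["f1"]}
        cells = [by_id[i] for i in chosen]
        assert len(cells) == len(set(cells))


class TestAugmentation:
    def test_one_image_four_variants(self):
        img = np.random.default_rng(0).uniform(0, 1, (6, 9, 3))
        variants = augment_scene(img, [(1.0, 2.0)])
        assert len(variants) == 4
        arrays = [v[1] for v in variants]
        for i in range(4):
            for j in range(i + 1, 4):
                if arrays[i].shape == arrays[j].shape:
                    assert not np.array_equal(arrays[i], arrays[j])

    def test_212_images_become_848(self):
        items = [(np.zeros((4, 4, 3)), [(1.0, 1.0)])] * 212
        assert len(augment_set(items)) == 848

    def test_transpose_maps_point_coordinates(self):
        img = np.random.default_rng(1).uniform(0, 1, (8, 12, 3))
        variants = dict((name, (im, pts)) for name, im, pts in augment_scene(img, [(2.0, 5.0)]))
        t_img, t_pts = variants["transpose"]
        assert t_img.shape[:2] == (12, 8)
        assert t_pts == [(5.0, 2.0)]

    def test_points_track_pixels_under_all_variants(self):
        """The pixel value under each transformed point equals the value
        under the original point."""
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (10, 14, 3))
        pts = [(3, 7), (9, 0)]
        for name, t_img, t_pts in augment_scene(img, pts):
            for (r0, c0), (r1, c1) in zip(pts, t_pts):
                assert np.array_equal(img[int(r0), int(c0)], t_img[int(r1), int(c1)])

    def test_counts_preserved_per_variant(self):
        img = np.zeros((6, 6, 3))
        pts = [(1.0, 2.0), (4.0, 4.0), (0.0, 5.0)]
        for _, _, t_pts in augment_scene(img, pts):
            assert len(t_pts) == 3


class TestSurveyOutputs:
    def _scheme(self):
        return build_range_scheme(60, 5)

    def test_histogram_counts_images_per_range(self):
        scheme = self._scheme()
        df = count_histogram([0, 5, 55, 58, 200], scheme)
        assert len(df) == 11
        freq = dict(zip(df["range"], df["n_images"]))
        assert freq[0] == 1 and freq[1] == 1 and freq[5] == 2 and freq[10] == 1

    def test_geojson_marker_per_positioned_record(self):
        scheme = self._scheme()
        records = make_field_records(
            {"a": 55, "b": 0, "c": 70},
            scheme,
            positions={"a": (56.1, 9.5), "b": (56.2, 9.6), "c": (56.3, 9.7)},
        )
        geo = field_map_geojson(records)
        assert geo["type"] == "FeatureCollection"
        assert len(geo["features"]) == 3
        colors = {f["properties"]["color"] for f in geo["features"]}
        assert len(colors) == 3  # three distinct ranges, three colors

    def test_missing_position_skipped_with_warning(self):
        scheme = self._scheme()
        records = make_field_records({"a": 55, "b": 10}, scheme, positions={"a": (56.0, 9.0)})
        with pytest.warns(UserWarning, match="position"):
            geo = field_map_geojson(records)
        assert len(geo["features"]) == 1

    def test_render_field_map_writes_files(self, tmp_path):
        scheme = self._scheme()
        records = make_field_records(
            {"a": 55, "b": 3}, scheme, positions={"a": (56.0, 9.0), "b": (56.1, 9.1)}
        )
        png = tmp_path / "map.png"
        gj = tmp_path / "map.geojson"
        render_field_map(records, scheme, png, gj)
        assert png.exists() and png.stat().st_size > 0
        loaded = json.loads(gj.read_text())
        assert len(loaded["features"]) == 2

    def test_empty_records_empty_map(self, tmp_path):
        scheme = self._scheme()
        geo = render_field_map([], scheme, tmp_path / "m.png", tmp_path / "m.geojson")
        assert geo["features"] == []
        assert (tmp_path / "m.png").exists()

    def test_records_frame_columns(self):
        scheme = self._scheme()
        df = records_to_frame(make_field_records({"a": 5}, scheme))
        assert list(df.columns) == ["image_id", "lat", "lon", "predicted_count", "range_label"]
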