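"""Rendering, segmentation, 3-class calling, lateral-position extraction."""

import math

import numpy as np
import pytest
from scipy import stats

from spiralsort import imaging as im
from spiralsort import sorter
from spiralsort.errors import ConfigError, InputError

DIAMETERS = {"enucleated": 8.0, "nucleated": 11.0, "nucleus": 6.0}


def matched_accuracy(objs, truth, um_per_px):
    """Fraction of planted objects whose nearest detection carries the right
    class, with spurious detections penalised through the denominator."""
    correct = 0
    for _, row in truth.iterrows():
        if not objs:
            break
        d2 = [
            (o.centroid_x_px - row.x_px) ** 2 + (o.centroid_y_px - row.y_px) ** 2
            for o in objs
        ]
        best = objs[int(np.argmin(d2))]
        if min(d2) <= (row.diameter_um / um_per_px) ** 2 and (
            best.assigned_class == row["class"]
        ):
            correct += 1
    return correct / max(len(objs), len(truth))


def grid_spec(classes, um_per_px=0.5, spacing=120, noise_sd=0.0, **kwargs):
    """Non-overlapping field with one object per requested class label."""
    per_row = 4
    objs = [
        im.PlantedObject(
            cls,
            60 + spacing * (i % per_row),
            60 + spacing * (i // per_row),
            DIAMETERS[cls],
        )
        for i, cls in enumerate(classes)
    ]
    rows = (len(classes) + per_row - 1) // per_row
    shape = (60 + spacing * rows, 60 + spacing * per_row)
    return im.SyntheticImageSpec(
        shape_px=shape, um_per_px=um_per_px, objects=objs, noise_sd=noise_sd, **kwargs
    )


class TestRenderCytospin:
    def test_empty_field(self):
        spec = im.SyntheticImageSpec(shape_px=(64, 64), um_per_px=0.5)
        img, truth = im.render_cytospin(spec)
        assert truth.empty
        assert np.ptp(img) == 0

    def test_truth_table_matches_objects(self):
        spec = grid_spec(["enucleated"] * 10 + ["nucleated"] * 5 + ["nucleus"] * 5)
        _, truth = im.render_cytospin(spec)
        assert len(truth) == 20

    def test_rendered_area_matches_disk(self):
        spec = grid_spec(["enucleated"])
        img, truth = im.render_cytospin(spec)
        objs = im.segment_objects(img, spec.um_per_px)
        expected = math.pi * DIAMETERS["enucleated"] ** 2 / 4
        assert objs[0].area_um2 == pytest.approx(expected, rel=0.05)

    def test_overlap_rejected_unless_allowed(self):
        objs = [
            im.PlantedObject("nucleus", 40, 40, 6.0),
            im.PlantedObject("nucleus", 43, 40, 6.0),
        ]
        spec = im.SyntheticImageSpec(shape_px=(80, 80), um_per_px=0.5, objects=objs)
        with pytest.raises(ConfigError):
            im.render_cytospin(spec)
        ok = im.SyntheticImageSpec(
            shape_px=(80, 80), um_per_px=0.5, objects=objs, allow_overlap=True
        )
        im.render_cytospin(ok)

    def test_object_must_fit_in_frame(self):
        spec = im.SyntheticImageSpec(
            shape_px=(32, 32),
            um_per_px=0.5,
            objects=[im.PlantedObject("nucleus", 2, 2, 6.0)],
        )
        with pytest.raises(ConfigError):
            im.render_cytospin(spec)

    def test_spread_factor_inflates_area(self):
        base = grid_spec(["enucleated"])
        spread = grid_spec(["enucleated"], spread_factors={"enucleated": 1.5})
        a0 = im.segment_objects(im.render_cytospin(base)[0], 0.5)[0].area_um2
        a1 = im.segment_objects(im.render_cytospin(spread)[0], 0.5)[0].area_um2
        assert a1 == pytest.approx(1.5 * a0, rel=0.05)


class TestSegmentObjects:
    def test_blank_image_yields_nothing(self):
        assert im.segment_objects(np.full((50, 50), 200, dtype=np.uint8), 0.5) == []

    def test_exact_count_on_planted_field(self):
        spec = grid_spec(["enucleated"] * 10 + ["nucleated"] * 5 + ["nucleus"] * 5)
        img, _ = im.render_cytospin(spec)
        assert len(im.segment_objects(img, spec.um_per_px)) == 20

    def test_min_area_filter_dominates(self):
        spec = grid_spec(["nucleus"] * 4)
        img, _ = im.render_cytospin(spec)
        assert im.segment_objects(img, spec.um_per_px, min_area_um2=1e4) == []

    def test_grayscale_required(self):
        with pytest.raises(InputError):
            im.segment_objects(np.zeros((4, 4, 3)), 0.5)


class TestClassifyObjects:
    def test_rules_on_rendered_field(self):
        spec = grid_spec(["enucleated"] * 6 + ["nucleated"] * 6 + ["nucleus"] * 8)
        img, _ = im.render_cytospin(spec)
        objs = im.segment_objects(img, spec.um_per_px)
        _, counts = im.classify_objects(objs)
        assert counts == {"enucleated": 6, "nucleated": 6, "nucleus": 8}

    def test_small_dark_object_is_nucleus(self):
        obj = im.SegmentedObject(0, 0, 0, 20.0, 5.0, 60.0, dark_fraction=1.0)
        _, counts = im.classify_objects([obj])
        assert counts["nucleus"] == 1

    def test_large_with_dark_core_is_nucleated(self):
        obj = im.SegmentedObject(0, 0, 0, 90.0, 11.0, 120.0, dark_fraction=0.3)
        objs, _ = im.classify_objects([obj], dark_fraction_cut=0.1)
        assert objs[0].assigned_class == "nucleated"

    def test_accuracy_degrades_gracefully_with_noise(self):
        classes = ["enucleated"] * 8 + ["nucleated"] * 8 + ["nucleus"] * 8
        accuracies = []
        for noise in (0.0, 30.0, 45.0):
            spec = grid_spec(classes, noise_sd=noise)
            img, truth = im.render_cytospin(spec, seed=12)
            objs = im.segment_objects(img, spec.um_per_px)
            objs, _ = im.classify_objects(objs)
            accuracies.append(matched_accuracy(objs, truth, spec.um_per_px))
        assert accuracies[0] >= 0.95
        assert accuracies[0] >= accuracies[1] >= accuracies[2]


class TestLateralPositions:
    SPEC = im.ChannelFrameSpec(wall_x_px=20.0, um_per_px=0.5)

    def test_geometry_identity(self):
        frame = im.render_channel_frame(self.SPEC, [36.0], diameter_um=4.0)
        pos, excluded = im.extract_lateral_positions(frame, self.SPEC)
        assert excluded == 0
        assert pos[0] == pytest.approx(36.0, abs=0.5)

    def test_blob_at_the_wall(self):
        frame = im.render_channel_frame(self.SPEC, [2.0], diameter_um=3.0)
        pos, _ = im.extract_lateral_positions(frame, self.SPEC)
        assert pos[0] == pytest.approx(2.0, abs=0.5)

    def test_wall_shift_is_affine(self):
        """Shifting the wall coordinate by k px shifts positions by k*scale."""
        frame = im.render_channel_frame(self.SPEC, [36.0, 80.0], diameter_um=4.0)
        shifted = im.ChannelFrameSpec(wall_x_px=10.0, um_per_px=0.5)
        p0, _ = im.extract_lateral_positions(frame, self.SPEC)
        p1, _ = im.extract_lateral_positions(frame, shifted)
        np.testing.assert_allclose(np.sort(p1) - np.sort(p0), 10.0 * 0.5, atol=1e-9)

    def test_planted_distribution_recovered(self):
        """200 in-channel blobs at normal(36, 21) positions: extraction matches
        the planted coordinates sub-pixel, and the truncation-aware fit
        recovers the underlying parameters within 3 standard errors."""
        rng = np.random.default_rng(np.random.SeedSequence(0))
        lo, hi = 2.0, 168.0
        a, b = (lo - 36) / 21, (hi - 36) / 21
        planted = stats.truncnorm.rvs(a, b, loc=36, scale=21, size=200, random_state=rng)
        frame = im.render_channel_frame(self.SPEC, planted, diameter_um=4.0)
        got, excluded = im.extract_lateral_positions(frame, self.SPEC)
        assert excluded == 0 and len(got) == 200
        assert np.max(np.abs(np.sort(got) - np.sort(planted))) < 0.5
        mu, sd = sorter.fit_position_model(got, lower=lo, upper=hi)
        assert abs(mu - 36.0) <= 3 * 21 / math.sqrt(200)
        assert abs(sd - 21.0) <= 3 * 21 / math.sqrt(2 * 200)

    def test_out_of_channel_detection_excluded(self):
        wide = im.ChannelFrameSpec(wall_x_px=200.0, um_per_px=0.5, channel_width_um=170.0)
        frame = im.render_channel_frame(wide, [50.0], diameter_um=4.0)
        narrow = im.ChannelFrameSpec(wall_x_px=320.0, um_per_px=0.5, channel_width_um=170.0)
        pos, excluded = im.extract_lateral_positions(frame, narrow)
        assert excluded == 1 and len(pos) == 0


class TestImageIO:
    def test_png_round_trip(self, tmp_path):
        spec = grid_spec(["nucleus"] * 2)
        img, _ = im.render_cytospin(spec)
        path = tmp_path / "field.png"
        im.write_image(img, path)
        back = im.read_image(path)
        np.testing.assert_array_equal(back, img)
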