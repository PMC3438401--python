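"""Deformed-geometry rasterisation, slice planning, and the FP/FN metric."""

import numpy as np
import pytest

from trabevalid import morphval as mv
from trabevalid.morphval import (MorphologyComparison, SlicePlanError,
                                 compare_slices, slice_plan, warp_labels)
from trabevalid.volume import BACKGROUND, BONE, CEMENT, MARKER, LabelVolume


def zero_field(label):
    return np.zeros(tuple(s + 1 for s in label.shape) + (3,))


@pytest.fixture()
def random_labels():
    rng = np.random.default_rng(0)
    lab = rng.choice([0, 0, BONE, CEMENT], size=(12, 10, 11)).astype(np.uint8)
    return LabelVolume(lab, 50.0)


class TestWarpLabels:
    def test_zero_displacement_identity(self, random_labels):
        out = warp_labels(random_labels, zero_field(random_labels))
        assert np.array_equal(out.labels, random_labels.labels)
        assert out.origin_mm == random_labels.origin_mm

    def test_integer_voxel_translation_exact(self, random_labels):
        field = zero_field(random_labels)
        field[..., 2] = 3 * random_labels.voxel_size_mm
        field[..., 0] = -2 * random_labels.voxel_size_mm
        out = warp_labels(random_labels, field)
        assert np.array_equal(out.labels, random_labels.labels)
        assert out.origin_mm[2] == pytest.approx(3 * random_labels.voxel_size_mm)
        assert out.origin_mm[0] == pytest.approx(-2 * random_labels.voxel_size_mm)

    def test_axial_strain_shrinks_extent(self):
        lab = np.full((100, 6, 6), BONE, np.uint8)
        lv = LabelVolume(lab, 50.0)
        field = mv.uniform_strain_field((101, 7, 7), 50.0, 0.03)
        out = warp_labels(lv, field)
        zs = np.flatnonzero(out.labels.any(axis=(1, 2)))
        assert abs((zs[-1] - zs[0] + 1) - 97) <= 1

    def test_rasterise_to_finer_grid(self):
        lab = np.full((10, 4, 4), CEMENT, np.uint8)
        lv = LabelVolume(lab, 50.0)
        out = warp_labels(lv, zero_field(lv), target_voxel_size_um=25.0)
        assert out.shape == (20, 8, 8)
        assert np.all(out.labels == CEMENT)

    def test_coarser_target_rejected(self, random_labels):
        with pytest.raises(ValueError):
            warp_labels(random_labels, zero_field(random_labels),
                        target_voxel_size_um=100.0)

    def test_cement_priority_on_overlap(self):
        # bone voxel translated onto a cement voxel: the overlap stays cement
        lab = np.zeros((1, 1, 3), np.uint8)
        lab[0, 0, 0] = BONE
        lab[0, 0, 2] = CEMENT
        lv = LabelVolume(lab, 100.0)
        field = zero_field(lv)
        field[:, :, :2, 0] = 0.2  # bone's own nodes shift by two voxels
        out = warp_labels(lv, field)
        ix = int(round((0.25 - out.origin_mm[0]) / 0.1 - 0.5))
        assert out.labels[0, 0, ix] == CEMENT

    def test_inverted_elements_warn(self):
        lab = np.full((1, 1, 1), BONE, np.uint8)
        lv = LabelVolume(lab, 100.0)
        field = zero_field(lv)
        field[1, ..., 2] = -0.2  # top face pushed through the bottom
        with pytest.warns(UserWarning, match="inverted"):
            warp_labels(lv, field)

    def test_field_shape_mismatch_rejected(self, random_labels):
        with pytest.raises(ValueError):
            warp_labels(random_labels, np.zeros((2, 2, 2, 3)))


class TestSlicePlan:
    def _volume_with_markers(self, xs_mm):
        from trabevalid.synthfoam import embed_markers
        lab = LabelVolume(np.zeros((40, 40, 40), np.uint8), 100.0)
        return embed_markers(lab, [(x, 2.0, 2.0) for x in xs_mm])

    def test_stations_equal_marker_centroids(self):
        vol = self._volume_with_markers([1.0, 2.0, 3.0])
        plan = slice_plan(vol)
        assert np.allclose(plan.stations_x_mm, [1.0, 2.0, 3.0], atol=0.1)

    def test_no_markers_fractional_defaults(self):
        vol = LabelVolume(np.zeros((10, 10, 20), np.uint8), 100.0)
        plan = slice_plan(vol)
        assert np.allclose(plan.stations_x_mm, [0.5, 1.0, 1.5])

    def test_wrong_marker_count_errors(self):
        vol = self._volume_with_markers([1.0, 2.0])
        with pytest.raises(SlicePlanError):
            slice_plan(vol)

    def test_stations_follow_translation(self):
        vol = self._volume_with_markers([1.0, 2.0, 3.0])
        shifted = LabelVolume(np.roll(vol.labels, 5, axis=2), 100.0)
        a = slice_plan(vol)
        b = slice_plan(shifted)
        shift = 5 * 0.1
        assert np.allclose(np.array(b.stations_x_mm),
                           np.array(a.stations_x_mm) + shift, atol=1e-6)

    def test_explicit_stations(self):
        plan = slice_plan(stations_mm=(0.5, 1.5, 2.5))
        assert plan.stations_x_mm == (0.5, 1.5, 2.5)

    def test_roundtrip_through_embedded_markers(self):
        # markers placed by the generator are recovered as slice stations
        vol = self._volume_with_markers([1.2, 2.0, 2.8])
        plan = slice_plan(vol)
        assert np.allclose(plan.stations_x_mm, [1.2, 2.0, 2.8], atol=0.1)


class TestCompareSlices:
    def test_identical_slices_zero_error(self):
        rng = np.random.default_rng(1)
        s = rng.choice([0, BONE, CEMENT], size=(50, 50)).astype(np.uint8)
        rec = compare_slices(s, s)
        assert rec.false_positive == 0
        assert rec.false_negative == 0
        assert rec.total_error_pct == 0.0

    def test_swap_symmetry_of_counts(self):
        rng = np.random.default_rng(2)
        a = rng.choice([0, BONE], size=(30, 30)).astype(np.uint8)
        b = rng.choice([0, CEMENT], size=(30, 30)).astype(np.uint8)
        r1 = compare_slices(a, b)
        r2 = compare_slices(b, a)
        assert r1.false_positive == r2.false_negative
        assert r1.false_negative == r2.false_positive

    def test_worked_pixel_count_example(self):
        # region 100 px, scan solid 60 px, model solid 70 px, 55 px overlap
        fe_s = np.zeros((10, 10), np.uint8)
        uct = np.zeros((10, 10), np.uint8)
        uct.ravel()[:60] = BONE
        fe_s.ravel()[5:75] = BONE
        rec = compare_slices(fe_s, uct)
        assert (rec.false_positive, rec.false_negative) == (15, 5)
        assert rec.denominator == 60
        assert rec.total_error_pct == pytest.approx(100 * 20 / 60, abs=0.01)

    def test_total_equals_fp_plus_fn(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.choice([0, BONE, CEMENT], size=(40, 40)).astype(np.uint8)
            b = rng.choice([0, BONE, CEMENT], size=(40, 40)).astype(np.uint8)
            r = compare_slices(a, b)
            assert r.total_error_pct == pytest.approx(r.fp_pct + r.fn_pct)

    def test_brute_force_oracle_random_slices(self):
        rng = np.random.default_rng(4)
        a = rng.choice([0, BONE, CEMENT, MARKER], size=(100, 100)).astype(np.uint8)
        b = rng.choice([0, BONE, CEMENT, MARKER], size=(100, 100)).astype(np.uint8)
        region = rng.random((100, 100)) < 0.8
        rec = compare_slices(a, b, region=region)
        fp = fn = match = denom = 0
        for i in range(100):
            for j in range(100):
                if not region[i, j] or a[i, j] == MARKER or b[i, j] == MARKER:
                    continue
                sa = a[i, j] in (BONE, CEMENT)
                sb = b[i, j] in (BONE, CEMENT)
                fp += sa and not sb
                fn += sb and not sa
                match += sa and sb
                denom += sb
        assert (rec.false_positive, rec.false_negative) == (fp, fn)
        assert (rec.match_solid, rec.denominator) == (match, denom)

    def test_marker_pixels_excluded(self):
        a = np.full((4, 4), BONE, np.uint8)
        b = np.full((4, 4), BONE, np.uint8)
        a[0, 0] = MARKER
        b[0, 0] = BACKGROUND  # would be FN were the marker not excluded
        rec = compare_slices(a, b)
        assert rec.false_negative == 0
        assert rec.denominator == 15

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_slices(np.zeros((3, 3), np.uint8),
                           np.zeros((4, 4), np.uint8))


class TestAggregate:
    def _rec(self, fp, fn, denom=1000, increment="step1"):
        return MorphologyComparison(denom - fp - fn, fp, fn, denom, increment)

    def test_single_record_mean_sd(self):
        table = mv.aggregate([self._rec(10, 5)])
        row = table.iloc[0]
        assert row.fp_mean == pytest.approx(1.0)
        assert row.fn_mean == pytest.approx(0.5)
        assert row.fp_sd == 0.0

    def test_mean_totals_add(self):
        # means of FP and FN percentages sum exactly to the mean total
        recs = [self._rec(20, 12), self._rec(25, 19), self._rec(22, 16)]
        table = mv.aggregate(recs)
        row = table.iloc[0]
        assert row.total_mean == pytest.approx(row.fp_mean + row.fn_mean)

    @pytest.mark.parametrize("fp_mean,fn_mean,total", [
        (2.25, 1.57, 3.82), (9.92, 7.95, 17.87)])
    def test_reported_style_totals(self, fp_mean, fn_mean, total):
        recs = [MorphologyComparison(0, int(fp_mean * 100), int(fn_mean * 100),
                                     10000, "s")]
        table = mv.aggregate(recs)
        assert table.iloc[0].total_mean == pytest.approx(total, abs=0.01)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mv.aggregate([])


class TestCalibrateUnloaded:
    def test_identical_inputs_zero(self):
        s = np.random.default_rng(5).choice(
            [0, BONE, CEMENT], size=(30, 30)).astype(np.uint8)
        recs = mv.calibrate_unloaded([s, s, s], [s, s, s])
        assert all(r.total_error_pct == 0.0 for r in recs)
        assert all(r.increment == "initial" for r in recs)

    def test_pure_resampling_error_small(self, capped_specimen):
        # rasterising the same geometry through a zero field at 2x finer
        # resolution: the only error is resampling, well under 2%
        field = np.zeros(tuple(s + 1 for s in capped_specimen.shape) + (3,))
        fine = warp_labels(capped_specimen, field, target_voxel_size_um=25.0)
        coarse_as_fine = np.repeat(np.repeat(np.repeat(
            capped_specimen.labels, 2, 0), 2, 1), 2, 2)
        stations = [fine.shape[2] // 4, fine.shape[2] // 2, 3 * fine.shape[2] // 4]
        recs = mv.calibrate_unloaded(
            [fine.labels[:, :, i] for i in stations],
            [coarse_as_fine[:, :, i] for i in stations])
        assert all(r.total_error_pct < 2.0 for r in recs)


def test_overlay_colors():
    fe_s = np.array([[BONE, 0], [BONE, MARKER]], np.uint8)
    uct = np.array([[BONE, BONE], [0, 0]], np.uint8)
    rgb = mv.overlay_rgb(fe_s, uct)
    assert tuple(rgb[0, 0]) == (0, 200, 0)    # match
    assert tuple(rgb[0, 1]) == (0, 0, 220)    # false negative
    assert tuple(rgb[1, 0]) == (220, 0, 0)    # false positive
    assert tuple(rgb[1, 1]) == (0, 0, 0)      # marker excluded
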