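"""Contour, curvature, tip, midline, width-sampling and de-tip checks
against analytic curves and generator ground truth."""

import numpy as np
import pytest

import taproot as tp
from taproot.errors import (
    DegenerateSegmentError,
    InsufficientDataError,
    NormalEscapeError,
)
from taproot.geometry import (
    Midline,
    WidthProfile,
    curvature,
    detip,
    find_tip,
    sample_widths,
    shoelace_area,
    straighten,
    train_detip,
)
from taproot.synth import training_profiles


def disk_mask(radius=50, pad=10):
    size = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:size, :size]
    c = radius + pad
    return tp.RootMask((yy - c) ** 2 + (xx - c) ** 2 <= radius**2)


class TestExtractContour:
    def test_square_area_and_perimeter(self):
        mask = tp.RootMask(np.pad(np.ones((10, 10), bool), 3))
        contour = tp.extract_contour(mask, smooth_sigma=0.0)
        assert abs(contour.area) == pytest.approx(100, abs=2)
        seg = np.diff(np.vstack([contour.points, contour.points[:1]]), axis=0)
        perimeter = np.hypot(seg[:, 0], seg[:, 1]).sum()
        # the 0.5 iso-level boundary cuts each corner diagonally, so the
        # perimeter sits between the pixel-edge count and the +4·0.71 bound
        assert 35.0 <= perimeter <= 40.0

    def test_disk_area_matches_circle(self):
        contour = tp.extract_contour(disk_mask(50))
        assert abs(contour.area) == pytest.approx(np.pi * 50**2, rel=0.01)

    def test_single_pixel_gives_smallest_loop(self):
        mask = tp.RootMask(np.pad(np.ones((1, 1), bool), 3))
        contour = tp.extract_contour(mask)
        assert contour.n_points >= 4
        assert np.all(np.hypot(*(contour.points - [3, 3]).T) <= 1.5)

    def test_orientation_is_positive_shoelace(self):
        for mask in (disk_mask(20), tp.RootMask(np.pad(np.ones((8, 5), bool), 2))):
            assert shoelace_area(tp.extract_contour(mask).points) > 0


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        theta = np.linspace(0, 2 * np.pi, 629, endpoint=False)
        pts = np.column_stack([100 * np.sin(theta), 100 * np.cos(theta)])
        k = curvature(pts, window=7, closed=True)
        assert np.all(np.abs(np.abs(k) - 0.01) < 1e-5)

    def test_collinear_points_have_zero_curvature(self):
        pts = np.column_stack([np.arange(100.0), 0.5 * np.arange(100.0)])
        assert np.allclose(curvature(pts, window=7), 0.0)

    def test_parabola_apex_curvature(self):
        x = np.linspace(-0.5, 0.5, 101)
        pts = np.column_stack([x**2 / 2, x])  # y = x^2/2 has K=1 at the apex
        k = curvature(pts, window=7)
        assert k[len(k) // 2] == pytest.approx(1.0, abs=1e-2)

    def test_sign_positive_on_convex_boundary(self):
        contour = tp.extract_contour(disk_mask(40))
        k = curvature(contour.points, window=7, closed=True)
        assert np.all(k > 0)

    def test_duplicate_points_raise(self):
        pts = np.zeros((30, 2))
        pts[:, 0] = np.arange(30.0)
        pts[10] = pts[9]
        with pytest.raises(DegenerateSegmentError):
            curvature(pts, window=7)


class TestFindTip:
    def test_pointed_root_tip_near_true_apex(self):
        mask, truth = tp.render_root(
            tp.RootShapeParams(length_px=400, max_width_px=80, fill_exponent=1.0,
                               tip_bluntness=0.0)
        )
        tip = find_tip(tp.extract_contour(mask))
        dist = np.hypot(tip.point[0] - truth.true_tip[0], tip.point[1] - truth.true_tip[1])
        assert dist <= 2.0
        assert not tip.low_confidence

    def test_blunt_root_tip_on_bottom_cap(self):
        mask, _ = tp.render_root(
            tp.RootShapeParams(length_px=400, max_width_px=80, fill_exponent=0.0,
                               tip_bluntness=1.0)
        )
        tip = find_tip(tp.extract_contour(mask))
        bottom = np.flatnonzero(mask.raster.any(axis=1))[-1]
        assert abs(tip.point[0] - bottom) <= 1.0

    def test_disk_is_low_confidence(self):
        tip = find_tip(tp.extract_contour(disk_mask(50)))
        assert tip.low_confidence


class TestTraceMidline:
    def test_rectangle_midline_is_the_center_line(self, rect_root, detip_model):
        mask, _ = rect_root
        tip = find_tip(tp.extract_contour(mask))
        midline = tp.trace_midline(mask, tip)
        cols = np.flatnonzero(mask.raster.any(axis=0))
        center = (cols[0] + cols[-1]) / 2
        assert np.max(np.abs(midline.points[:, 1] - center)) <= 1.0

    def test_bent_root_midline_tracks_generated_midline(self):
        mask, truth = tp.render_root(
            tp.RootShapeParams(length_px=500, max_width_px=80, fill_exponent=1.0,
                               tip_bluntness=0.5, bend_amplitude_px=30,
                               bend_wavelength_px=700)
        )
        midline = tp.trace_midline(mask, find_tip(tp.extract_contour(mask)))
        # mean distance from each true midline point to the traced one
        d = np.min(
            np.hypot(
                truth.true_midline[:, None, 0] - midline.points[None, :, 0],
                truth.true_midline[:, None, 1] - midline.points[None, :, 1],
            ),
            axis=1,
        )
        assert d.mean() <= 2.0

    def test_bent_arc_length_exceeds_straight_row_extent(self):
        mask, truth = tp.render_root(
            tp.RootShapeParams(length_px=500, max_width_px=70, tip_bluntness=0.5,
                               bend_amplitude_px=40, bend_wavelength_px=500)
        )
        midline = tp.trace_midline(mask, find_tip(tp.extract_contour(mask)))
        rows = np.flatnonzero(mask.raster.any(axis=1))
        assert midline.arc_length_px > (rows[-1] - rows[0]) * 1.02
        assert midline.arc_length_px == pytest.approx(truth.true_length_px, rel=0.02)


class TestSampleWidths:
    def test_rectangle_widths_constant(self, rect_root):
        mask, _ = rect_root
        midline = tp.trace_midline(mask, find_tip(tp.extract_contour(mask)))
        profile = sample_widths(mask, midline)
        interior = profile.widths_px[5:-5]
        assert np.all(np.abs(interior - 50) <= 1.0)

    def test_bend_does_not_inflate_widths(self):
        # normal sampling must agree with the generating width function even
        # on a bent root; row-wise sampling would overestimate by 1/cos(tilt)
        mask, truth = tp.render_root(
            tp.RootShapeParams(length_px=500, max_width_px=80, fill_exponent=1.0,
                               tip_bluntness=0.5, bend_amplitude_px=30,
                               bend_wavelength_px=700)
        )
        midline = tp.trace_midline(mask, find_tip(tp.extract_contour(mask)))
        profile = sample_widths(mask, midline)
        true_w = truth.true_width_function
        idx = np.arange(25, 475)
        rel = np.abs(profile.widths_px[idx] - true_w[idx]) / true_w[idx]
        assert rel.max() <= 0.03

    def test_taper_rate_recovered(self):
        mask, truth = tp.render_root(
            tp.RootShapeParams(length_px=500, max_width_px=100, fill_exponent=1.0,
                               tip_bluntness=0.2)
        )
        midline = tp.trace_midline(mask, find_tip(tp.extract_contour(mask)))
        profile = sample_widths(mask, midline)
        idx = np.arange(25, 475)
        slope = np.polyfit(idx, profile.widths_px[idx], 1)[0]
        true_slope = (truth.true_width_function[-1] - truth.true_width_function[0]) / 499
        assert slope == pytest.approx(true_slope, rel=0.05)

    def test_mask_touching_border_raises(self):
        mask = tp.RootMask(np.ones((60, 30), bool))
        midline = Midline(np.column_stack([np.arange(59.0, 0.0, -1.0), np.full(59, 15.0)]))
        with pytest.raises(NormalEscapeError):
            sample_widths(mask, midline)


class TestStraighten:
    def test_rectangle_straightens_to_itself(self, rect_root):
        mask, _ = rect_root
        midline = tp.trace_midline(mask, find_tip(tp.extract_contour(mask)))
        straight = straighten(sample_widths(mask, midline))
        rows = straight.raster.shape[0]
        run = straight.raster.sum(axis=1)
        assert rows == pytest.approx(200, abs=4)
        assert np.all(np.abs(run[5:-5] - 50) <= 1)

    def test_explicit_widths_render_exact_runs(self):
        straight = straighten(WidthProfile(np.array([4.0, 4.0, 2.0])))
        assert straight.raster.shape[0] == 3
        assert straight.area_px == 10

    def test_area_conserved_on_bent_root(self):
        mask, _ = tp.render_root(
            tp.RootShapeParams(length_px=500, max_width_px=80, fill_exponent=1.0,
                               tip_bluntness=0.5, bend_amplitude_px=30,
                               bend_wavelength_px=700)
        )
        midline = tp.trace_midline(mask, find_tip(tp.extract_contour(mask)))
        straight = straighten(sample_widths(mask, midline))
        assert straight.area_px == pytest.approx(mask.area_px, rel=0.02)

    def test_reversed_profile_straightens_to_flipped_raster(self):
        widths = np.linspace(80, 20, 200)
        a = straighten(WidthProfile(widths))
        b = straighten(WidthProfile(widths[::-1]))
        assert np.array_equal(a.raster, b.raster[::-1])


class TestDetip:
    def test_heldout_cut_accuracy(self, detip_model):
        pairs = training_profiles(100, seed=97)  # held out from training seed
        errs = [
            abs(detip_model.predict_cut(p) - cut) * 1000.0 / cut for p, cut in pairs
        ]
        assert np.median(errs) <= 5.0

    def test_no_tail_profiles_cut_at_end(self, detip_model):
        pairs = [(p, c) for p, c in training_profiles(200, seed=55) if c == len(p)]
        assert len(pairs) >= 30
        at_end = [abs(detip_model.predict_cut(p) - len(p)) <= 3 for p, _ in pairs]
        assert np.mean(at_end) >= 0.95

    def test_abrupt_drop_is_found(self, detip_model):
        widths = np.concatenate([np.full(600, 60.0), np.full(60, 4.0)])
        cut = detip_model.predict_cut(WidthProfile(widths))
        assert abs(cut - 600) <= 3

    def test_detip_is_idempotent(self, detip_model):
        profile = WidthProfile(np.concatenate([np.full(300, 50.0), np.full(40, 4.0)]))
        once = detip(profile, detip_model)
        twice = detip(once, detip_model)
        assert twice.cut_index == once.cut_index
        assert np.array_equal(twice.widths_px, profile.widths_px)

    def test_training_is_reproducible(self):
        pairs = training_profiles(60, seed=5)
        m1 = train_detip(pairs, seed=9)
        m2 = train_detip(pairs, seed=9)
        probe = training_profiles(10, seed=6)
        assert [m1.predict_cut(p) for p, _ in probe] == [
            m2.predict_cut(p) for p, _ in probe
        ]

    def test_too_few_examples_raise(self):
        with pytest.raises(InsufficientDataError):
            train_detip(training_profiles(10, seed=0))
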