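"""Image and time-course quantification: channel subtraction, compartment
masks, normalizations, AUC."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import memprobe as mp
from memprobe.quant import (
    ChannelImage, ImageStack, RoiMask, area_under_curve, compartment_mask,
    masked_intensity_timecourse, normalize_timecourse, normalized_subtraction,
    rim_band, subtract_camera_offset,
)


def image(pixels, subtracted=True):
    return ChannelImage(pixels=np.asarray(pixels, float), pixel_size=0.1,
                        offset_subtracted=subtracted)


def square_roi(size, margin):
    roi = np.zeros((size, size), bool)
    roi[margin:size - margin, margin:size - margin] = True
    return roi


# ---------------------------------------------------------------------------
# camera offset
# ---------------------------------------------------------------------------

class TestCameraOffset:
    def test_uniform_subtraction(self):
        out = subtract_camera_offset(image(np.full((4, 4), 100.0), False), 20.0)
        np.testing.assert_array_equal(out.pixels, 80.0)
        assert out.offset_subtracted

    def test_zero_offset_identity(self):
        out = subtract_camera_offset(image(np.full((4, 4), 7.0), False), 0.0)
        np.testing.assert_array_equal(out.pixels, 7.0)

    def test_floor_and_clip_count(self):
        px = np.array([[5.0, 30.0], [10.0, 50.0]])
        out = subtract_camera_offset(image(px, False), 20.0)
        np.testing.assert_array_equal(out.pixels, [[0.0, 10.0], [0.0, 30.0]])
        assert out.n_clipped == 2

    def test_double_subtraction_rejected(self):
        once = subtract_camera_offset(image(np.ones((2, 2)), False), 0.0)
        with pytest.raises(ValueError):
            subtract_camera_offset(once, 5.0)

    def test_stack_variant(self):
        stack = ImageStack(frames=np.full((3, 4, 4), 50.0), pixel_size=0.1,
                           frame_interval=1.0)
        out = subtract_camera_offset(stack, 20.0)
        np.testing.assert_array_equal(out.frames, 30.0)


# ---------------------------------------------------------------------------
# normalized subtraction
# ---------------------------------------------------------------------------

class TestNormalizedSubtraction:
    def test_identical_channels_give_zero(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(50, 150, size=(32, 32))
        roi = RoiMask(square_roi(32, 4))
        res = normalized_subtraction(image(px), image(px.copy()), roi, 2)
        np.testing.assert_allclose(res.subtracted, 0.0, atol=1e-12)
        assert res.rim_mean == pytest.approx(0.0, abs=1e-12)

    def test_rim_enrichment_hand_arithmetic(self):
        # 10x10 ROI, rim_width=1: erosion rim has 36 px, interior 64 px.
        # Biosensor: 100 inside, 200 on rim -> ROI mean 136.
        roi_mask = np.zeros((16, 16), bool)
        roi_mask[3:13, 3:13] = True
        rim = rim_band(roi_mask, 1)
        assert rim.sum() == 36
        ref = np.zeros((16, 16))
        ref[roi_mask] = 100.0
        bio = ref.copy()
        bio[rim] = 200.0
        res = normalized_subtraction(image(bio), image(ref), RoiMask(roi_mask), 1)
        assert res.rim_mean == pytest.approx(200.0 / 136.0 - 1.0)
        assert res.roi_mean == pytest.approx(0.0, abs=1e-12)
        interior = roi_mask & ~rim
        np.testing.assert_allclose(res.subtracted[interior], 100.0 / 136.0 - 1.0)

    def test_exposure_scale_invariance(self):
        rng = np.random.default_rng(1)
        bio = rng.uniform(10, 200, (24, 24))
        ref = rng.uniform(10, 200, (24, 24))
        roi = RoiMask(square_roi(24, 3))
        a = normalized_subtraction(image(bio), image(ref), roi, 2)
        b = normalized_subtraction(image(2 * bio), image(2 * ref), roi, 2)
        np.testing.assert_allclose(a.subtracted, b.subtracted, atol=1e-12)
        assert a.rim_mean == pytest.approx(b.rim_mean)

    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 10.0))
    def test_roi_mean_zero_and_scaling_property(self, seed, scale):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(16, 40))
        margin = int(rng.integers(2, size // 4))
        roi = RoiMask(square_roi(size, margin))
        cfg = mp.ConfocalPhantomConfig(
            image_shape=(size, size), roi=roi.mask,
            rim_width=1, rim_enrichment=float(rng.uniform(0.5, 4.0)),
            cytosol_level=float(rng.uniform(50, 200)),
            noise_model="gaussian", noise_sigma=2.0,
            seed=int(rng.integers(2 ** 31)),
        )
        bio, ref, roim, _ = mp.synthesize_confocal_pair(cfg)
        b = subtract_camera_offset(bio, 0.0)
        r = subtract_camera_offset(ref, 0.0)
        res = normalized_subtraction(b, r, roim, 1)
        assert abs(res.roi_mean) < 1e-9
        b2 = image(b.pixels * scale)
        r2 = image(r.pixels * scale)
        res2 = normalized_subtraction(b2, r2, roim, 1)
        np.testing.assert_allclose(res2.subtracted, res.subtracted,
                                   rtol=1e-9, atol=1e-9)

    def test_requires_offset_subtraction(self):
        roi = RoiMask(square_roi(16, 3))
        with pytest.raises(ValueError):
            normalized_subtraction(image(np.ones((16, 16)), subtracted=False),
                                   image(np.ones((16, 16))), roi, 1)

    def test_erosion_emptying_roi_rejected(self):
        roi = RoiMask(square_roi(16, 7))  # 2x2 ROI
        img = image(np.ones((16, 16)))
        with pytest.raises(ValueError):
            normalized_subtraction(img, image(np.ones((16, 16))), roi, 3)


# ---------------------------------------------------------------------------
# compartment masks
# ---------------------------------------------------------------------------

def otsu_oracle(values):
    """Exhaustive integer-threshold search maximizing between-class variance."""
    best_t, best_v = None, -1.0
    for t in range(int(values.min()), int(values.max())):
        lo, hi = values[values <= t], values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / values.size, hi.size / values.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


class TestCompartmentMask:
    def test_two_valued_marker_exact(self):
        px = np.full((20, 20), 10.0)
        px[5:8, 5:8] = 200.0
        roi = RoiMask(np.ones((20, 20), bool))
        got = compartment_mask(image(px), roi, min_size=1)
        np.testing.assert_array_equal(got.mask, px == 200.0)

    def test_min_size_filters_everything(self):
        px = np.full((20, 20), 10.0)
        px[5:7, 5:7] = 200.0
        roi = RoiMask(np.ones((20, 20), bool))
        got = compartment_mask(image(px), roi, min_size=50)
        assert got.empty

    def test_uniform_marker_gives_empty_flag(self):
        roi = RoiMask(np.ones((8, 8), bool))
        got = compartment_mask(image(np.full((8, 8), 42.0)), roi)
        assert got.empty

    @given(hnp.arrays(np.uint8, (12, 12),
                      elements=st.integers(0, 255)))
    def test_otsu_equals_exhaustive_search(self, px):
        roi = RoiMask(np.ones((12, 12), bool))
        vals = px.astype(float)
        t = otsu_oracle(px.ravel())
        if t is None:  # constant image
            assert compartment_mask(image(vals), roi, min_size=1).empty
            return
        got = compartment_mask(image(vals), roi, min_size=1)
        np.testing.assert_array_equal(got.mask, vals > t)

    def test_fixed_threshold(self):
        px = np.arange(16.0).reshape(4, 4)
        roi = RoiMask(np.ones((4, 4), bool))
        got = compartment_mask(image(px), roi, method="fixed",
                               fixed_threshold=10.0, min_size=1)
        np.testing.assert_array_equal(got.mask, px > 10.0)


# ---------------------------------------------------------------------------
# masked intensity time course
# ---------------------------------------------------------------------------

def stacks(reporter_frames, marker_frames):
    mk = lambda f: ImageStack(frames=np.asarray(f, float), pixel_size=0.1,
                              frame_interval=1.0, offset_subtracted=True)
    return mk(reporter_frames), mk(marker_frames)


class TestMaskedTimecourse:
    def test_uniform_reporter_ratio_one(self):
        n, size = 6, 20
        marker = np.full((n, size, size), 10.0)
        marker[:, 4:7, 4:7] = 200.0
        reporter = np.full((n, size, size), 55.0)
        rep, mark = stacks(reporter, marker)
        roi = RoiMask(np.ones((size, size), bool))
        tc = masked_intensity_timecourse(rep, mark, roi, pre_frames=[0, 1],
                                         min_size=1)
        np.testing.assert_allclose(tc.raw, 1.0)
        np.testing.assert_allclose(tc.normalized["f_over_fpre"], 1.0)

    def test_hand_arithmetic_ratio(self):
        # puncta cover 10% of the ROI at 150, the rest at 50:
        # ratio = 150 / (0.1*150 + 0.9*50) = 2.5
        size = 20  # ROI = 400 px; 40 puncta px = 10%
        marker = np.full((2, size, size), 10.0)
        marker[:, 0:4, 0:10] = 200.0
        reporter = np.full((2, size, size), 50.0)
        reporter[:, 0:4, 0:10] = 150.0
        rep, mark = stacks(reporter, marker)
        roi = RoiMask(np.ones((size, size), bool))
        tc = masked_intensity_timecourse(rep, mark, roi, pre_frames=[0],
                                         min_size=1)
        np.testing.assert_allclose(tc.raw, 2.5)

    def test_empty_mask_frame_is_missing_value(self):
        size = 16
        marker = np.full((3, size, size), 10.0)
        marker[0, 2:5, 2:5] = 200.0
        marker[2, 2:5, 2:5] = 200.0  # frame 1 has no puncta
        reporter = np.full((3, size, size), 50.0)
        rep, mark = stacks(reporter, marker)
        roi = RoiMask(np.ones((size, size), bool))
        tc = masked_intensity_timecourse(rep, mark, roi, pre_frames=[0],
                                         min_size=1)
        assert np.isnan(tc.raw[1])
        assert np.isfinite(tc.raw[[0, 2]]).all()

    def test_phantom_recruitment_recovers_analytic_plateau(self):
        from memprobe.simkit import Kinetics, PunctaSpec, TimeSeriesPhantomConfig
        roi_mask = square_roi(48, 8)
        spec = PunctaSpec(n_puncta=6, radius_px=3, marker_level=200.0,
                          recruitment=3.0,
                          kinetics=Kinetics(kind="step", plateau=3.0))
        cfg = TimeSeriesPhantomConfig(
            image_shape=(48, 48), roi=roi_mask, n_frames=10,
            frame_interval=2.0, treatment_frame=4, puncta=spec,
            cytosol_level=100.0, seed=5,
        )
        rep, mark, labels = mp.synthesize_compartment_movie(cfg)
        rep = subtract_camera_offset(rep, 0.0)
        mark = subtract_camera_offset(mark, 0.0)
        tc = masked_intensity_timecourse(rep, mark, RoiMask(roi_mask),
                                         pre_frames=list(range(4)))
        n_punct = int((labels[0] > 0).sum())
        n_roi = int(roi_mask.sum())
        # analytic mask/ROI ratio before and after recruitment
        pre_ratio = 1.0
        post_ratio = 3.0 * n_roi / (n_roi - n_punct + 3.0 * n_punct)
        np.testing.assert_allclose(tc.raw[:4], pre_ratio, atol=1e-6)
        np.testing.assert_allclose(tc.raw[4:], post_ratio, atol=1e-6)


# ---------------------------------------------------------------------------
# time-course normalization and AUC
# ---------------------------------------------------------------------------

class TestNormalizeTimecourse:
    TRACE = [10.0, 10.0, 8.0, 6.0]

    def test_f_over_fpre(self):
        tc = normalize_timecourse(self.TRACE, [0, 1], "f_over_fpre")
        np.testing.assert_allclose(tc.normalized["f_over_fpre"],
                                   [1.0, 1.0, 0.8, 0.6])

    def test_minmax(self):
        tc = normalize_timecourse(self.TRACE, [0, 1], "minmax")
        np.testing.assert_allclose(tc.normalized["minmax"], [1.0, 1.0, 0.5, 0.0])

    def test_delta_over_deltamax(self):
        tc = normalize_timecourse(self.TRACE, [0, 1], "delta_over_deltamax")
        np.testing.assert_allclose(tc.normalized["delta_over_deltamax"],
                                   [0.0, 0.0, -0.5, -1.0])

    def test_constant_trace_f_over_fpre_is_one(self):
        tc = normalize_timecourse([5.0] * 6, [0, 1, 2], "f_over_fpre")
        np.testing.assert_allclose(tc.normalized["f_over_fpre"], 1.0)

    def test_constant_trace_minmax_degenerate(self):
        with pytest.raises(ValueError):
            normalize_timecourse([5.0] * 6, [0, 1], "minmax")

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_timecourse([0.0, 0.0, 1.0], [0, 1], "f_over_fpre")

    def test_pre_frames_must_precede_treatments(self):
        with pytest.raises(ValueError):
            normalize_timecourse([1.0, 2.0, 3.0], [0, 1, 2], "f_over_fpre",
                                 frame_interval=1.0,
                                 treatments=[(1.5, "drug")])

    @given(st.integers(0, 2 ** 31 - 1))
    def test_normalization_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        raw = rng.uniform(1.0, 100.0, size=n)
        n_pre = int(rng.integers(1, n))
        pre = list(range(n_pre))
        f = normalize_timecourse(raw, pre, "f_over_fpre").normalized["f_over_fpre"]
        assert f[pre].mean() == pytest.approx(1.0)
        if np.ptp(raw) > 0:
            m = normalize_timecourse(raw, pre, "minmax").normalized["minmax"]
            assert m.min() == 0.0 and m.max() == 1.0


class TestAreaUnderCurve:
    def tc(self, raw, dt=1.0):
        return normalize_timecourse(raw, [0], "f_over_fpre", frame_interval=dt)

    def test_constant_one_over_ten_seconds(self):
        tc = self.tc([1.0] * 11)
        assert area_under_curve(tc, (0.0, 10.0)) == pytest.approx(10.0)

    def test_self_baseline_zero(self):
        tc = self.tc([1.0] * 11)
        assert area_under_curve(tc, (0.0, 10.0), baseline=1.0) == pytest.approx(0.0)

    def test_triangle_ramp(self):
        tc = self.tc(list(np.linspace(1.0, 0.0, 11)))
        assert area_under_curve(tc, (0.0, 10.0)) == pytest.approx(5.0)

    def test_interpolated_endpoints(self):
        tc = self.tc([1.0] * 11)
        assert area_under_curve(tc, (2.5, 7.5)) == pytest.approx(5.0)

    def test_window_outside_span_rejected(self):
        tc = self.tc([1.0] * 5)
        with pytest.raises(ValueError):
            area_under_curve(tc, (0.0, 10.0))

    def test_empty_window_rejected(self):
        tc = self.tc([1.0] * 5)
        with pytest.raises(ValueError):
            area_under_curve(tc, (2.0, 2.0))
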