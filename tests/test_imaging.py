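import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tectotune import (DffTrace, RoiRecord, SizeTuningProfile,
                       assign_ap_region, compute_dff, count_size_classes,
                       cumulative_wmr, delta_wmr, extract_roi_trace,
                       is_responsive, median_wmr, phase_correlation_shift,
                       size_responses, smooth_median3, wmr_angle)
from tectotune.errors import (AlignmentError, ConfigurationError,
                              DegenerateBaselineError, UndefinedShiftError,
                              UndefinedWmrError)
from tectotune.imaging import WmrRecord

SIZES = np.array([2.0, 5.0, 10.0, 20.0, 30.0])


def profile(responses, sizes=SIZES, responsive=True):
    return SizeTuningProfile(roi_id=0, sizes_deg=sizes,
                             mean_response=np.asarray(responses, float),
                             responsive=responsive)


# ---------------------------------------------------------------------------
# ΔF/F
# ---------------------------------------------------------------------------

class TestComputeDff:
    def test_constant_trace_maps_to_zero(self, tiny_protocol):
        rec = RoiRecord(0, (0, 0), np.full(tiny_protocol.n_frames, 100.0))
        assert np.allclose(compute_dff(rec, tiny_protocol).dff, 0.0)

    def test_direct_evaluation(self, tiny_protocol):
        # baseline frames {100, 100}, a later frame at 150 -> ΔF/F = 0.5
        raw = np.array([100.0, 100.0, 150.0, 100.0, 100.0])
        dff = compute_dff(RoiRecord(0, (0, 0), raw), tiny_protocol).dff
        assert dff[2] == pytest.approx(0.5)

    def test_baseline_is_mean_of_pre_frames(self, tiny_protocol):
        raw = np.array([90.0, 110.0, 100.0, 100.0, 100.0])
        dff = compute_dff(RoiRecord(0, (0, 0), raw), tiny_protocol).dff
        assert dff[2] == pytest.approx(0.0)

    def test_degenerate_baseline_rejected(self, tiny_protocol):
        raw = np.array([-1.0, 1.0, 5.0, 5.0, 5.0])
        with pytest.raises(DegenerateBaselineError):
            compute_dff(RoiRecord(0, (0, 0), raw), tiny_protocol)

    def test_length_mismatch_rejected(self, tiny_protocol):
        with pytest.raises(AlignmentError):
            compute_dff(RoiRecord(0, (0, 0), np.ones(7)), tiny_protocol)


class TestSmoothMedian3:
    def test_constant_unchanged(self):
        out = smooth_median3(DffTrace(0, np.full(10, 0.3)))
        assert np.array_equal(out.dff, np.full(10, 0.3))
        assert out.smoothed

    def test_single_frame_spike_removed(self):
        out = smooth_median3(DffTrace(0, np.array([0.0, 10.0, 0.0])))
        assert out.dff[1] == 0.0

    def test_matches_brute_force_sliding_median(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=51)
        out = smooth_median3(DffTrace(0, x)).dff
        expected = np.array([
            np.median(x[max(0, t - 1):t + 2]) for t in range(x.size)])
        assert np.allclose(out, expected)

    def test_monotone_sequence_interior_unchanged(self):
        x = np.arange(20.0)
        out = smooth_median3(DffTrace(0, x)).dff
        assert np.array_equal(out[1:-1], x[1:-1])


class TestResponsivenessGate:
    @pytest.mark.parametrize("peak,expected", [
        (0.0, False), (0.5, True), (0.49, False), (0.51, True)])
    def test_threshold_is_inclusive(self, peak, expected):
        trace = DffTrace(0, np.array([0.0, peak, 0.0]), smoothed=True)
        assert is_responsive(trace) is expected


class TestSizeResponses:
    def test_zero_trace_gives_zero_profile(self, default_protocol):
        trace = DffTrace(0, np.zeros(default_protocol.n_frames))
        prof = size_responses(trace, default_protocol)
        assert np.array_equal(prof.mean_response, np.zeros(5))
        assert not prof.responsive

    def test_indicator_response_isolates_one_size(self, default_protocol):
        dff = np.zeros(default_protocol.n_frames)
        for start, stop in default_protocol.stim_windows(10.0):
            dff[start:stop] = 1.0
        prof = size_responses(DffTrace(0, dff), default_protocol)
        by_size = dict(zip(prof.sizes_deg, prof.mean_response))
        assert by_size[10.0] == pytest.approx(1.0)
        for size in (2.0, 5.0, 20.0, 30.0):
            assert by_size[size] == 0.0

    def test_length_mismatch_rejected(self, default_protocol):
        with pytest.raises(AlignmentError):
            size_responses(DffTrace(0, np.zeros(10)), default_protocol)


# ---------------------------------------------------------------------------
# the WMR statistic
# ---------------------------------------------------------------------------

class TestWmrAngle:
    def test_point_mass(self):
        assert wmr_angle(profile([0, 0, 1, 0, 0])) == 10.0

    def test_equal_responses(self):
        # 10 ** (mean of log10 sizes) = 9.0288...
        expected = 10 ** (np.log10(SIZES).mean())
        assert wmr_angle(profile([1, 1, 1, 1, 1])) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(9.03, abs=0.01)

    def test_two_point_weights(self):
        # weights 0.75 on 2° and 0.25 on 20° -> 10^(0.75 log2 + 0.25 log20)
        got = wmr_angle(profile([0.75, 0, 0, 0.25, 0]))
        assert got == pytest.approx(3.5566, abs=1e-3)

    def test_all_nonpositive_is_undefined(self):
        with pytest.raises(UndefinedWmrError):
            wmr_angle(profile([0, 0, 0, 0, 0]))
        with pytest.raises(UndefinedWmrError):
            wmr_angle(profile([-1, -2, 0, -0.5, 0]))

    def test_negative_responses_clamped_to_zero(self):
        assert wmr_angle(profile([-5, 0, 1, 0, -3])) == \
            wmr_angle(profile([0, 0, 1, 0, 0]))

    @given(st.lists(st.floats(0, 100), min_size=5, max_size=5)
           .filter(lambda r: sum(r) > 1e-9))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bound_and_scale_invariance(self, responses):
        w = wmr_angle(profile(responses))
        assert SIZES[0] <= w <= SIZES[-1] + 1e-12
        scaled = wmr_angle(profile([3.7 * r for r in responses]))
        assert scaled == pytest.approx(w, rel=1e-9)

    def test_mass_transfer_to_larger_size_increases_wmr(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            r = rng.uniform(0.1, 1.0, 5)
            i, j = sorted(rng.choice(5, size=2, replace=False))
            moved = r.copy()
            delta = 0.5 * r[i]
            moved[i] -= delta
            moved[j] += delta
            assert wmr_angle(profile(moved)) > wmr_angle(profile(r))


class TestCumulativeAndMedian:
    def test_single_neuron(self):
        curve = cumulative_wmr(np.array([9.0]))
        assert curve.angles_deg.tolist() == [9.0]
        assert curve.cumulative_pct.tolist() == [100.0]
        assert median_wmr(curve) == pytest.approx(9.0)

    def test_two_neurons_geometric_midpoint(self):
        curve = cumulative_wmr(np.array([20.0, 5.0]))
        assert curve.cumulative_pct.tolist() == [50.0, 100.0]
        assert median_wmr(curve) == pytest.approx(10.0)

    def test_ecdf_definition(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(2, 30, 17)
        curve = cumulative_wmr(angles)
        assert np.array_equal(curve.angles_deg, np.sort(angles))
        assert np.allclose(curve.cumulative_pct,
                           100 * np.arange(1, 18) / 17)
        assert curve.cumulative_pct[-1] == 100.0

    def test_odd_n_median_is_middle_order_statistic(self):
        angles = np.array([3.0, 25.0, 7.0, 12.0, 4.0])
        assert median_wmr(cumulative_wmr(angles)) == pytest.approx(7.0)

    def test_median_matches_sort_based_percentile_oracle(self):
        rng = np.random.default_rng(9)
        for n in (2, 5, 10, 33):
            angles = rng.uniform(2, 30, n)
            expected = 10 ** np.percentile(np.log10(angles), 50)
            assert median_wmr(cumulative_wmr(angles)) == pytest.approx(
                expected, rel=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cumulative_wmr(np.array([]))


# ---------------------------------------------------------------------------
# registration and extraction
# ---------------------------------------------------------------------------

class TestPhaseCorrelation:
    def test_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(32, 32))
        assert phase_correlation_shift(img, img) == (0, 0)

    def test_known_cyclic_shift_recovered_and_nulled(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(64, 64))
        frame = np.roll(ref, shift=(-2, 3), axis=(0, 1))
        dx, dy = phase_correlation_shift(frame, ref)
        realigned = np.roll(frame, shift=(dy, dx), axis=(0, 1))
        assert np.allclose(realigned, ref)
        assert phase_correlation_shift(realigned, ref) == (0, 0)

    def test_matches_exhaustive_correlation_oracle(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(64, 64))
        frame = np.roll(ref, shift=(7, -5), axis=(0, 1)) \
            + 0.05 * rng.normal(size=(64, 64))
        best, best_val = None, -np.inf
        for sy in range(-8, 9):
            for sx in range(-8, 9):
                val = float(np.sum(ref * np.roll(frame, (sy, sx), (0, 1))))
                if val > best_val:
                    best, best_val = (sx, sy), val
        assert phase_correlation_shift(frame, ref) == best

    def test_constant_image_rejected(self):
        with pytest.raises(UndefinedShiftError):
            phase_correlation_shift(np.ones((8, 8)), np.zeros((8, 8)))


class TestExtractRoiTrace:
    def test_uniform_roi_sums_pixels(self):
        mask = np.zeros((10, 10), dtype=np.uint16)
        mask[2:7, 2:7] = 3  # 25-pixel ROI
        stack = np.full((4, 10, 10), 4.0)
        rec = extract_roi_trace(stack, mask, 3)
        assert np.array_equal(rec.raw_f, np.full(4, 100.0))
        assert rec.centroid_xy == (4.0, 4.0)

    def test_single_pixel_roi(self):
        mask = np.zeros((5, 5), dtype=np.uint16)
        mask[1, 3] = 7
        stack = np.arange(3 * 25, dtype=float).reshape(3, 5, 5)
        rec = extract_roi_trace(stack, mask, 7)
        assert np.array_equal(rec.raw_f, stack[:, 1, 3])

    def test_absent_roi_raises(self):
        with pytest.raises(KeyError):
            extract_roi_trace(np.zeros((2, 5, 5)),
                              np.zeros((5, 5), dtype=np.uint16), 4)


# ---------------------------------------------------------------------------
# topography
# ---------------------------------------------------------------------------

class TestApRegion:
    AXIS = ((10.0, 10.0), (110.0, 60.0))

    def test_axis_endpoints(self):
        assert assign_ap_region((10, 10), self.AXIS) == (1.0, "anterior")
        assert assign_ap_region((110, 60), self.AXIS) == (10.0, "posterior")

    def test_midpoint_is_medial(self):
        scale, region = assign_ap_region((60, 35), self.AXIS)
        assert scale == pytest.approx(5.5)
        assert region == "medial"

    def test_boundaries_fall_into_lower_bin(self):
        # scale exactly 3 -> anterior, exactly 6 -> medial
        axis = ((0.0, 0.0), (9.0, 0.0))
        assert assign_ap_region((2.0, 0.0), axis) == (3.0, "anterior")
        assert assign_ap_region((5.0, 0.0), axis) == (6.0, "medial")

    def test_projection_clipped_to_axis(self):
        axis = ((0.0, 0.0), (9.0, 0.0))
        assert assign_ap_region((-4.0, 2.0), axis)[0] == 1.0
        assert assign_ap_region((40.0, -2.0), axis)[0] == 10.0

    def test_zero_length_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_ap_region((1, 1), ((5, 5), (5, 5)))


class TestDeltaWmr:
    def rec(self, angle, region):
        return WmrRecord(0, angle, 5.0, region)

    def test_identical_sessions_give_zero(self):
        session = [self.rec(5.0, "anterior"), self.rec(9.0, "posterior")]
        out = delta_wmr(session, session)
        assert out["anterior"] == 0.0
        assert out["posterior"] == 0.0

    def test_uniform_shift_recovered(self):
        pre = [self.rec(5.0, "anterior"), self.rec(7.0, "anterior")]
        post = [self.rec(8.0, "anterior"), self.rec(10.0, "anterior")]
        assert delta_wmr(pre, post)["anterior"] == pytest.approx(3.0)

    def test_missing_region_flagged_not_raised(self):
        pre = [self.rec(5.0, "anterior")]
        post = [self.rec(6.0, "posterior")]
        out = delta_wmr(pre, post)
        assert all(np.isnan(v) for v in out.values())


class TestCountSizeClasses:
    def make(self, peak_size, responsive=True):
        resp = (SIZES == peak_size).astype(float)
        return SizeTuningProfile(0, SIZES, resp, responsive)

    def test_all_small(self):
        out = count_size_classes([self.make(2.0)] * 4)
        assert (out["n_small"], out["n_large"]) == (4, 0)
        assert out["frac_small"] == 1.0

    def test_none_responsive(self):
        out = count_size_classes([self.make(2.0, responsive=False)] * 3)
        assert (out["n_small"], out["n_large"], out["n_responsive"]) == \
            (0, 0, 0)

    def test_mixed_classes(self):
        profiles = [self.make(2.0), self.make(5.0), self.make(10.0),
                    self.make(30.0)]
        out = count_size_classes(profiles)
        assert (out["n_small"], out["n_large"]) == (2, 2)
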