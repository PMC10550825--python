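import numpy as np
import pytest

from gluimg.errors import (
    ClassificationRefusedError,
    DataError,
    MotionEstimationError,
    PairingError,
    ParameterError,
)
from gluimg.invivo import (
    MotionEstimate,
    PeakTrain,
    apply_stabilization,
    bandpass_trace,
    classify_invivo_cell,
    compare_blocker_periods,
    detect_peaks,
    estimate_motion,
    extract_roi_traces,
    hotspot_overlap,
    roi_response,
    segment_rois,
)
from gluimg.invivo import RoiSet

FRAME_MS = 30.0


def _blob_frame(size=64, value=400.0, background=50.0, at=(28, 28), blob=8):
    frame = np.full((size, size), background, dtype=np.float64)
    y, x = at
    frame[y:y + blob, x:x + blob] += value
    return frame


def _train(times_s, frame_period_ms=FRAME_MS):
    frames = np.round(np.asarray(times_s) * 1000.0 / frame_period_ms).astype(int)
    return PeakTrain(
        peak_frames=frames,
        peak_amplitudes_z=np.full(len(frames), 3.0),
        fwhm_ms=np.full(len(frames), 300.0),
        frame_period_ms=frame_period_ms,
    )


class TestEstimateMotion:
    def test_motionless_stack(self):
        stack = np.tile(_blob_frame(), (6, 1, 1))
        est = estimate_motion(stack)
        assert np.all(est.shifts == 0.0)
        assert est.keep_mask.all() and est.n_kept == 6

    def test_featureless_stack_raises(self):
        stack = np.full((4, 64, 64), 50.0)
        with pytest.raises(MotionEstimationError):
            estimate_motion(stack)

    def test_recovers_known_integer_shift(self):
        base = _blob_frame()
        stack = np.tile(base, (8, 1, 1))
        stack[5] = np.roll(np.roll(base, 3, axis=0), -2, axis=1)
        est = estimate_motion(stack)
        assert tuple(est.shifts[5]) == (3.0, -2.0)
        assert est.keep_mask[5]  # 3 px is within the 5 px gate

    def test_large_shift_excluded(self):
        base = _blob_frame()
        stack = np.tile(base, (8, 1, 1))
        stack[2] = np.roll(base, 8, axis=0)
        est = estimate_motion(stack)
        assert not est.keep_mask[2]
        assert est.keep_mask.sum() == 7

    def test_parameter_gates(self):
        stack = np.tile(_blob_frame(), (3, 1, 1))
        with pytest.raises(ParameterError):
            estimate_motion(stack, contrast_threshold=0.5)
        with pytest.raises(ParameterError):
            estimate_motion(stack, mode="affine")
        with pytest.raises(ParameterError):
            estimate_motion(stack[:, :16, :16])  # FOV too small for the margin


class TestApplyStabilization:
    def test_identity_for_zero_shifts(self, rng):
        stack = rng.random((5, 16, 16))
        est = MotionEstimate(np.zeros((5, 2)), np.ones(5, dtype=bool))
        out, index_map = apply_stabilization(stack, est)
        assert np.allclose(out, stack)
        assert np.array_equal(index_map, np.arange(5))

    def test_restores_shifted_frame(self):
        base = _blob_frame()
        stack = np.stack([base, np.roll(np.roll(base, 3, axis=0), -2, axis=1)])
        est = MotionEstimate(np.array([[0.0, 0.0], [3.0, -2.0]]),
                             np.ones(2, dtype=bool))
        out, _ = apply_stabilization(stack, est)
        interior = (slice(4, -4), slice(4, -4))
        assert np.allclose(out[1][interior], base[interior])

    def test_drops_excluded_frames(self, rng):
        stack = rng.random((6, 16, 16))
        keep = np.array([True, True, False, True, False, True])
        est = MotionEstimate(np.zeros((6, 2)), keep)
        out, index_map = apply_stabilization(stack, est)
        assert out.shape[0] == 4
        assert np.array_equal(index_map, [0, 1, 3, 5])


class TestSegmentRois:
    def _map_with_blobs(self, peaks, blob=3, size=64, spacing=8):
        amap = np.zeros((size, size))
        positions = []
        for k, p in enumerate(peaks):
            y = 4 + (k * spacing) // (size - blob - 8) * spacing
            x = 4 + (k * spacing) % (size - blob - 8)
            amap[y:y + blob, x:x + blob] = p
            positions.append((y, x))
        return amap, positions

    def test_counts_and_ranking(self):
        peaks = [9.0, 5.0, 7.0, 3.0, 8.0]
        amap, _ = self._map_with_blobs(peaks)
        rois = segment_rois(amap, n_max=50, min_pixels=5)
        assert len(rois) == 5
        assert list(rois.activity) == sorted(peaks, reverse=True)
        # masks are disjoint and each covers its full 3x3 blob
        total = sum(int(m.sum()) for m in rois.masks)
        assert total == 5 * 9

    def test_small_component_excluded(self):
        amap = np.zeros((64, 64))
        amap[10:13, 10:13] = 6.0  # 9 px, kept
        amap[40:42, 40:42] = 9.0  # 4 px, below min_pixels=5
        rois = segment_rois(amap, n_max=50, min_pixels=5)
        assert len(rois) == 1 and int(rois.masks[0].sum()) == 9

    def test_cap_keeps_strongest(self):
        peaks = [9.0, 5.0, 7.0, 3.0, 8.0]
        amap, _ = self._map_with_blobs(peaks)
        rois = segment_rois(amap, n_max=3, min_pixels=5)
        assert len(rois) == 3
        assert list(rois.activity) == [9.0, 8.0, 7.0]
        assert rois.status == "ok"

    def test_empty_map(self):
        rois = segment_rois(np.zeros((32, 32)))
        assert len(rois) == 0 and rois.status == "empty"

    def test_roiset_validation(self):
        big = np.ones((8, 8), dtype=bool)
        with pytest.raises(DataError):
            RoiSet([big[:1, :3]], np.array([1.0]), min_pixels=5)
        with pytest.raises(DataError):
            RoiSet([big, big], np.array([1.0]))


class TestExtractTraces:
    def test_identical_pixels_give_standardized_trace(self, rng):
        t = 200
        trace = rng.standard_normal(t)
        stack = np.zeros((t, 8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2, 2:7] = True  # 5 identical pixels
        stack[:, mask] = trace[:, None]
        stack[:, ~mask] = rng.standard_normal((t, 64 - 5))
        rois = RoiSet([mask], np.array([1.0]))
        out = extract_roi_traces(stack, rois)
        assert out.shape == (1, t)
        assert out[0].mean() == pytest.approx(0.0, abs=1e-12)
        assert out[0].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        expected = (trace - trace.mean()) / trace.std(ddof=0)
        assert np.allclose(out[0], expected)

    def test_independent_rois_uncorrelated(self, rng):
        t = 2000
        stack = rng.standard_normal((t, 8, 8))
        m1 = np.zeros((8, 8), dtype=bool)
        m2 = np.zeros((8, 8), dtype=bool)
        m1[0, :5] = True
        m2[7, :5] = True
        out = extract_roi_traces(stack, RoiSet([m1, m2], np.array([1.0, 1.0])))
        r = np.corrcoef(out)[0, 1]
        assert abs(r) < 0.2

    def test_constant_roi_rejected(self):
        stack = np.ones((10, 8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[0, :5] = True
        with pytest.raises(DataError):
            extract_roi_traces(stack, RoiSet([mask], np.array([1.0])))


class TestBandpass:
    N = 1000  # 30 s at 30 ms: rfft bins at k/30 Hz

    def _tone(self, period_s):
        t = np.arange(self.N) * FRAME_MS / 1000.0
        return np.sin(2 * np.pi * t / period_s)

    def test_slow_tone_removed(self):
        out = bandpass_trace(self._tone(5.0), FRAME_MS)  # 0.2 Hz, below 0.5 Hz edge
        assert np.abs(out).max() < 1e-10

    def test_in_band_tone_preserved(self):
        tone = self._tone(0.5)  # 2 Hz, inside [0.5, 6.67] Hz
        out = bandpass_trace(tone, FRAME_MS)
        assert np.abs(out).max() / np.abs(tone).max() > 0.9

    def test_blocker_band_passes_slow_tone(self):
        tone = self._tone(5.0)  # 0.2 Hz, inside the blocker band [0.1, 2] Hz
        out = bandpass_trace(tone, FRAME_MS, min_event_ms=500.0, max_event_ms=10000.0)
        assert np.abs(out).max() / np.abs(tone).max() > 0.9

    def test_zero_phase_peak_alignment(self):
        trace = np.zeros(self.N)
        trace[500] = 1.0
        out = bandpass_trace(trace, FRAME_MS)
        assert int(np.argmax(out)) == 500

    def test_trace_too_short(self):
        with pytest.raises(ParameterError):
            bandpass_trace(np.zeros(50), FRAME_MS)  # 1.5 s < the 2 s band edge

    def test_empty_band(self):
        # 1.2 s trace: bins every 0.833 Hz miss the [6.45, 6.62] Hz band
        with pytest.raises(ParameterError):
            bandpass_trace(np.zeros(40), FRAME_MS, min_event_ms=151.0,
                           max_event_ms=155.0)

    def test_invalid_band(self):
        with pytest.raises(ParameterError):
            bandpass_trace(np.zeros(self.N), FRAME_MS, min_event_ms=500.0,
                           max_event_ms=400.0)


def _gaussian_pulse(fwhm_ms, amp=3.0, n=400, center=200):
    sigma_frames = fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)) * FRAME_MS)
    k = np.arange(n)
    return amp * np.exp(-0.5 * ((k - center) / sigma_frames) ** 2)


class TestDetectPeaks:
    def test_flat_trace_empty(self):
        train = detect_peaks(np.zeros(100), FRAME_MS)
        assert len(train.peak_frames) == 0

    def test_wide_pulse_detected_with_fwhm(self):
        train = detect_peaks(_gaussian_pulse(400.0), FRAME_MS)
        assert len(train.peak_frames) == 1
        assert train.peak_frames[0] == 200
        assert train.fwhm_ms[0] == pytest.approx(400.0, abs=FRAME_MS)

    def test_narrow_pulse_rejected_by_width(self):
        train = detect_peaks(_gaussian_pulse(150.0), FRAME_MS)
        assert len(train.peak_frames) == 0

    def test_low_amplitude_rejected(self):
        train = detect_peaks(_gaussian_pulse(400.0, amp=1.5), FRAME_MS,
                             restandardize=False)
        assert len(train.peak_frames) == 0

    def test_frequency_two_pulses(self):
        trace = _gaussian_pulse(400.0, center=100) + _gaussian_pulse(
            400.0, center=100 + int(round(1000.0 / FRAME_MS))
        )
        train = detect_peaks(trace, FRAME_MS)
        assert len(train.peak_frames) == 2
        # two peaks in the first 10 s of kept time
        assert train.frequency_hz((0.0, 10.0)) == pytest.approx(0.2)

    def test_restandardization_rescues_busy_trace(self, rng):
        # noise + many events: the plain SD is event-inflated, the MAD is not
        n = 2000
        trace = 0.2 * rng.standard_normal(n)
        for c in range(100, n - 100, 150):
            trace += _gaussian_pulse(400.0, amp=1.0, n=n, center=c)
        raw = detect_peaks(trace, FRAME_MS, restandardize=False)
        std = detect_peaks(trace, FRAME_MS, restandardize=True)
        assert len(std.peak_frames) > len(raw.peak_frames)
        assert len(std.peak_frames) >= 10

    def test_zero_length_window_rejected(self):
        train = _train([1.0, 2.0])
        with pytest.raises(ParameterError):
            train.frequency_hz((5.0, 5.0))


class TestRoiResponse:
    def test_clear_increase(self):
        train = _train([1, 3, 5, 7] + [11, 12, 13, 14, 15, 16])
        ok, base, stim = roi_response(train, (0.0, 10.0), (10.0, 20.0))
        assert ok and base == pytest.approx(0.4) and stim == pytest.approx(0.6)

    def test_sub_threshold_increase(self):
        base_times = list(np.linspace(0.5, 19.5, 8))  # 0.4 Hz over 20 s
        stim_times = list(np.linspace(20.5, 39.5, 9))  # 0.45 Hz < 0.4 * 1.25
        ok, _, _ = roi_response(_train(base_times + stim_times),
                                (0.0, 20.0), (20.0, 40.0))
        assert not ok

    def test_silent_baseline_single_peak(self):
        ok, base, stim = roi_response(_train([12.0]), (0.0, 10.0), (10.0, 20.0))
        assert ok and base == 0.0 and stim == pytest.approx(0.1)

    def test_doubling_flag_probability_monte_carlo(self):
        # Poisson trains, 0.2 Hz baseline vs 0.4 Hz effect, 120 s windows:
        # the >25% rule should flag the doubling in >= 80% of draws
        flagged = 0
        n_trials = 50
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            base_times = rng.uniform(0.0, 120.0, rng.poisson(0.2 * 120))
            stim_times = rng.uniform(120.0, 240.0, rng.poisson(0.4 * 120))
            train = _train(np.sort(np.concatenate([base_times, stim_times])))
            ok, _, _ = roi_response(train, (0.0, 120.0), (120.0, 240.0))
            flagged += ok
        assert flagged / n_trials >= 0.80


class TestClassify:
    FOV = 100 * 100

    def _masks(self, n, pixels):
        masks = []
        for k in range(n):
            m = np.zeros((100, 100), dtype=bool)
            r = k * 4
            m.flat[r * 100:r * 100 + pixels] = True
            masks.append(m)
        return masks

    def test_strong_responder(self):
        # 8 ROIs of 200 px (16% total), every ROI more than doubles
        trains = []
        for k in range(8):
            base = list(np.linspace(0.5, 9.5, 2))
            stim = list(np.linspace(10.5, 19.5, 5 + k))
            trains.append(_train(base + stim))
        res = classify_invivo_cell(
            trains, self._masks(8, 200), self.FOV,
            stim_onset_s=10.0, total_duration_s=30.0,
        )
        assert res.responder
        assert res.area_fraction == pytest.approx(0.16)
        assert res.p_value < 0.05
        assert res.baseline_window_s == (0.0, 10.0)

    def test_small_area_blocks_responder(self):
        # same strong frequency effect, but responsive ROIs cover only 1.6%
        trains = []
        for k in range(8):
            base = list(np.linspace(0.5, 9.5, 2))
            stim = list(np.linspace(10.5, 19.5, 5 + k))
            trains.append(_train(base + stim))
        res = classify_invivo_cell(
            trains, self._masks(8, 20), self.FOV,
            stim_onset_s=10.0, total_duration_s=30.0,
        )
        assert not res.responder
        assert res.p_value < 0.05  # significant, rejected on area alone
        assert res.area_fraction == pytest.approx(0.016)

    def test_no_effect_not_responder(self):
        trains = [
            _train(np.linspace(0.5, 29.5, 6 + (k % 2))) for k in range(8)
        ]
        res = classify_invivo_cell(
            trains, self._masks(8, 200), self.FOV,
            stim_onset_s=10.0, total_duration_s=30.0,
        )
        assert not res.responder

    def test_effect_window_slides_to_late_activity(self):
        # peaks cluster 20-30 s; the scan should pick that window, not (10, 20)
        trains = []
        for k in range(8):
            stim = list(np.linspace(20.5, 29.5, 6 + k))
            trains.append(_train([1.0, 5.0] + stim))
        res = classify_invivo_cell(
            trains, self._masks(8, 200), self.FOV,
            stim_onset_s=10.0, total_duration_s=40.0,
        )
        assert res.effect_window_s == (20.0, 30.0)
        assert res.responder

    def test_too_few_rois_refused(self):
        trains = [_train([1.0, 12.0]) for _ in range(5)]
        with pytest.raises(ClassificationRefusedError):
            classify_invivo_cell(
                trains, self._masks(5, 200), self.FOV,
                stim_onset_s=10.0, total_duration_s=30.0,
            )

    def test_timing_validation(self):
        trains = [_train([1.0]) for _ in range(8)]
        with pytest.raises(ParameterError):
            classify_invivo_cell(trains, self._masks(8, 200), self.FOV,
                                 stim_onset_s=25.0, total_duration_s=30.0)


class TestHotspotOverlap:
    def _mask(self, y, x, size=5, fov=64):
        m = np.zeros((fov, fov), dtype=bool)
        m[y:y + size, x:x + size] = True
        return m

    def test_identical_sets(self):
        rois = [self._mask(10, 10), self._mask(40, 40)]
        out = hotspot_overlap(rois, [m.copy() for m in rois], (64, 64))
        assert out["status"] == "ok" and out["fraction"] == 1.0
        assert out["hotspot_map"].any()

    def test_disjoint_sets(self):
        out = hotspot_overlap([self._mask(5, 5)], [self._mask(50, 50)], (64, 64))
        assert out["fraction"] == 0.0
        assert not out["hotspot_map"].any()

    def test_partial_overlap_fraction(self):
        # smaller set has 4 ROIs, 3 of which overlap the other set
        set_a = [self._mask(5, 5), self._mask(5, 30), self._mask(30, 5),
                 self._mask(30, 30), self._mask(55, 55)]
        set_b = [self._mask(5, 5), self._mask(5, 30), self._mask(30, 5),
                 self._mask(45, 45)]
        out = hotspot_overlap(set_a, set_b, (64, 64))
        assert out["fraction"] == pytest.approx(3 / 4)
        assert out["n_overlapping"] == 3

    def test_empty_set_undefined(self):
        out = hotspot_overlap([], [self._mask(5, 5)], (64, 64))
        assert out["status"] == "undefined" and out["fraction"] is None


class TestBlockerComparison:
    def test_identical_frequencies_p_one(self):
        f = np.array([0.1, 0.2, 0.3, 0.15, 0.25, 0.2])
        assert compare_blocker_periods(f, f.copy())["p_value"] == 1.0

    def test_pairing_errors(self):
        with pytest.raises(PairingError):
            compare_blocker_periods(np.zeros(4), np.zeros(5))
        with pytest.raises(PairingError):
            compare_blocker_periods(np.array([]), np.array([]))

    def test_clear_decrease_detected(self):
        rng = np.random.default_rng(3)
        pre = 0.2 + 0.02 * rng.standard_normal(12)
        post = pre / 2.0 + 0.005 * rng.standard_normal(12)
        out = compare_blocker_periods(pre, post)
        assert out["p_value"] < 0.05
        assert out["mean_post_hz"] < out["mean_pre_hz"]

    def test_null_type_one_error_rate(self):
        # trace-level null: identical white-noise statistics in both halves.
        # blocker band, peak detection, paired test on 8 ROI frequencies.
        n = 2000  # 60 s at 30 ms
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            pre, post = [], []
            for _ in range(8):
                trace = rng.standard_normal(n)
                filt = bandpass_trace(trace, FRAME_MS, min_event_ms=500.0,
                                      max_event_ms=10000.0)
                train = detect_peaks(filt, FRAME_MS)
                pre.append(train.frequency_hz((0.0, 30.0)))
                post.append(train.frequency_hz((30.0, 60.0)))
            p = compare_blocker_periods(np.array(pre), np.array(post))["p_value"]
            rejections += p < 0.05
        # nominal level 0.05; the signed-rank test on 8 pairs is discrete and
        # conservative, so the empirical rate should not exceed ~2x nominal
        assert rejections / n_seeds <= 0.10
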