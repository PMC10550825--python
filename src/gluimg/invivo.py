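"""Awake-mouse analysis: motion gating, ROI segmentation and event-frequency
responder rules.

Pipeline: estimate rigid frame shifts from the static red morphology channel
(Gaussian-smoothed, contrast-thresholded, normalised cross-correlation
against the time-averaged template) and drop frames displaced by more than
5 px on either axis; z-score the stabilized green channel per pixel; segment
up to 50 disjoint ROIs (>= 5 px) from a per-pixel activity map; band-pass
each ROI trace to the event band (150 ms - 2 s periods; 500 ms - 10 s in
blocker mode); detect peaks > 2z lasting > 250 ms FWHM; flag ROIs whose peak
frequency rises by > 25% after the stimulus; and call the cell a responder
when responsive ROIs cover >= 3% of the FOV and the paired per-ROI frequency
change is significant (two-sided Wilcoxon signed-rank, p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats
from skimage import measure
from skimage.feature import match_template

from .errors import (
    ClassificationRefusedError,
    DataError,
    MotionEstimationError,
    PairingError,
    ParameterError,
)
from .preprocess import zscore_stack

__all__ = [
    "MotionEstimate",
    "RoiSet",
    "PeakTrain",
    "InVivoCellResult",
    "estimate_motion",
    "apply_stabilization",
    "activity_map",
    "segment_rois",
    "extract_roi_traces",
    "bandpass_trace",
    "detect_peaks",
    "roi_response",
    "classify_invivo_cell",
    "hotspot_overlap",
    "compare_blocker_periods",
    "run_invivo_pipeline",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class MotionEstimate:
    """Per-frame rigid shifts (dy, dx) and the frames safe to analyse."""

    shifts: np.ndarray  # (t, 2) estimated (dy, dx) in pixels
    keep_mask: np.ndarray  # (t,) bool
    max_shift_px: float = 5.0
    mode: str = "per_axis"  # or "euclidean"

    def __post_init__(self):
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.keep_mask = np.asarray(self.keep_mask, dtype=bool)
        if self.shifts.shape != (len(self.keep_mask), 2):
            raise DataError("shifts and keep_mask disagree in length")

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())


@dataclass
class RoiSet:
    """Disjoint connected pixel masks ranked by activity."""

    masks: list  # boolean (y, x) arrays
    activity: np.ndarray  # per-ROI peak of the activity map
    min_pixels: int = 5
    n_max: int = 50
    status: str = "ok"
    threshold: float = float("nan")

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if len(self.masks) != len(self.activity):
            raise DataError("masks and activity ranks disagree in length")
        if len(self.masks) > self.n_max:
            raise DataError("more masks than n_max")
        for m in self.masks:
            if int(np.asarray(m).sum()) < self.min_pixels:
                raise DataError("ROI below the minimum pixel count")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def total_pixels(self) -> int:
        return int(sum(np.asarray(m).sum() for m in self.masks))


@dataclass
class PeakTrain:
    """Detected peaks of one ROI trace."""

    peak_frames: np.ndarray  # indices into the (kept-frame) trace
    peak_amplitudes_z: np.ndarray
    fwhm_ms: np.ndarray
    frame_period_ms: float

    def __post_init__(self):
        self.peak_frames = np.asarray(self.peak_frames, dtype=int)
        self.peak_amplitudes_z = np.asarray(self.peak_amplitudes_z, dtype=float)
        self.fwhm_ms = np.asarray(self.fwhm_ms, dtype=float)
        if not (
            len(self.peak_frames) == len(self.peak_amplitudes_z) == len(self.fwhm_ms)
        ):
            raise DataError("peak train arrays disagree in length")

    @property
    def peak_times_s(self) -> np.ndarray:
        return self.peak_frames * self.frame_period_ms / 1000.0

    def frequency_hz(self, window_s: tuple[float, float]) -> float:
        """Peaks per second within [t0, t1) of kept time."""
        t0, t1 = window_s
        if t1 <= t0:
            raise ParameterError("zero-length frequency window")
        times = self.peak_times_s
        return float(np.count_nonzero((times >= t0) & (times < t1)) / (t1 - t0))


@dataclass
class InVivoCellResult:
    baseline_freqs_hz: np.ndarray
    stim_freqs_hz: np.ndarray
    response_flags: np.ndarray
    area_fraction: float
    p_value: float
    responder: bool
    baseline_window_s: tuple
    effect_window_s: tuple
    qc_flags: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# motion
# --------------------------------------------------------------------------


def _contrast_frames(
    stack: np.ndarray, smooth_sigma: float, contrast_threshold: float
) -> np.ndarray:
    """Per-frame normalise (F / F_mean), smooth and zero the low-contrast floor."""
    stack = np.asarray(stack, dtype=np.float32)
    means = stack.mean(axis=(1, 2), dtype=np.float64)
    if np.any(means <= 0):
        raise DataError("red channel contains frames with non-positive mean")
    norm = stack / means[:, None, None].astype(np.float32)
    smooth = ndimage.gaussian_filter(norm, sigma=(0, smooth_sigma, smooth_sigma))
    return np.where(smooth >= contrast_threshold, smooth, 0.0)


def estimate_motion(
    red_stack: np.ndarray,
    smooth_sigma: float = 3.0,
    contrast_threshold: float = 1.2,
    max_shift_px: float = 5.0,
    search_margin_px: int = 12,
    mode: str = "per_axis",
) -> MotionEstimate:
    """Per-frame rigid shift of the red morphology structure.

    The time-averaged high-contrast image, cropped by ``search_margin_px``,
    serves as the template; each frame's shift is the offset of its
    normalised cross-correlation peak.  ``keep_mask`` is false where the
    shift magnitude exceeds ``max_shift_px`` (per axis by default,
    Euclidean with ``mode="euclidean"``).
    """
    red_stack = np.asarray(red_stack)
    if red_stack.ndim != 3:
        raise ParameterError("expected a 3-D (t, y, x) red stack")
    if not (1.0 <= contrast_threshold <= 1.5):
        raise ParameterError("contrast_threshold must lie in [1.0, 1.5]")
    if mode not in ("per_axis", "euclidean"):
        raise ParameterError("mode must be 'per_axis' or 'euclidean'")
    n, h, w = red_stack.shape
    margin = int(search_margin_px)
    if margin < max_shift_px:
        raise ParameterError("search margin must cover the exclusion threshold")
    if 2 * margin + 8 > min(h, w):
        raise ParameterError("FOV too small for the requested search margin")

    contrast = _contrast_frames(red_stack, smooth_sigma, contrast_threshold)
    template_full = contrast.mean(axis=0)
    template = template_full[margin:h - margin, margin:w - margin]
    if template.max() <= 0 or template.std() == 0:
        raise MotionEstimationError(
            "morphology template is featureless after contrast thresholding"
        )

    shifts = np.zeros((n, 2), dtype=float)
    for i in range(n):
        corr = match_template(contrast[i], template)
        peak = np.unravel_index(np.argmax(corr), corr.shape)
        # peak at (margin, margin) means the structure sits at the template
        # position; the frame is displaced by (peak - margin)
        shifts[i] = (peak[0] - margin, peak[1] - margin)

    if mode == "per_axis":
        keep = np.all(np.abs(shifts) <= max_shift_px, axis=1)
    else:
        keep = np.hypot(shifts[:, 0], shifts[:, 1]) <= max_shift_px
    return MotionEstimate(shifts=shifts, keep_mask=keep, max_shift_px=max_shift_px, mode=mode)


def apply_stabilization(
    stack: np.ndarray, motion: MotionEstimate
) -> tuple[np.ndarray, np.ndarray]:
    """Translate each kept frame by the negated integer shift.

    Returns the stabilized stack (kept frames only) and the index map from
    stabilized frame number to original frame number.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != len(motion.keep_mask):
        raise ParameterError("stack does not match the motion estimate")
    index_map = np.flatnonzero(motion.keep_mask)
    out = np.empty((len(index_map),) + stack.shape[1:], dtype=np.float32)
    for j, i in enumerate(index_map):
        dy, dx = np.round(motion.shifts[i]).astype(int)
        if dy == 0 and dx == 0:
            out[j] = stack[i]
        else:
            out[j] = ndimage.shift(
                stack[i].astype(np.float32), (-dy, -dx), order=0, mode="nearest"
            )
    return out, index_map


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------


def activity_map(z_stack: np.ndarray, metric: str = "robust") -> np.ndarray:
    """Per-pixel activity over the stabilized acquisition.

    metric:
      "robust" (default) — peak excursion in noise units,
        (max - median) / (1.4826 * MAD); unlike the plain z maximum it is
        not deflated for pixels whose temporal SD is inflated by frequent
        events, so busy pixels rank above noise.
      "max"  — plain per-pixel maximum of the z trace.
      "p99"  — per-pixel 99th percentile of the z trace.
    """
    z_stack = np.asarray(z_stack)
    if z_stack.ndim != 3:
        raise ParameterError("expected a 3-D (t, y, x) z-stack")
    if metric == "max":
        return z_stack.max(axis=0)
    if metric == "p99":
        return np.percentile(z_stack, 99, axis=0)
    if metric == "robust":
        med = np.median(z_stack, axis=0)
        mad = np.median(np.abs(z_stack - med[None]), axis=0)
        scale = 1.4826 * mad
        out = np.zeros(z_stack.shape[1:], dtype=np.float64)
        ok = scale > 0
        out[ok] = (z_stack.max(axis=0)[ok] - med[ok]) / scale[ok]
        return out
    raise ParameterError(f"unknown activity metric {metric!r}")


def _components(binary: np.ndarray, min_pixels: int) -> list[np.ndarray]:
    labels = measure.label(binary, connectivity=2)
    masks = []
    for lab in range(1, labels.max() + 1):
        m = labels == lab
        if int(m.sum()) >= min_pixels:
            masks.append(m)
    return masks


def segment_rois(
    green_activity_map: np.ndarray,
    n_max: int = 50,
    min_pixels: int = 5,
    n_threshold_steps: int = 80,
    floor_quantile: float = 0.80,
) -> RoiSet:
    """Up to ``n_max`` disjoint ROIs from the activity map.

    The binarisation threshold is scanned from the map maximum down to the
    ``floor_quantile`` level.  Among all candidate thresholds, the lowest one
    still yielding at least ``n_max`` connected components of ``min_pixels``
    or more is used, so each ROI covers its whole contiguous active region
    rather than just its brightest core; when no threshold reaches ``n_max``
    components, the lowest threshold attaining the maximum count is used.
    Components are ranked by their peak activity, ties broken by centroid
    position; the top ``n_max`` are returned.  Fewer eligible components than
    requested is reported in ``status``, an empty map yields an empty set.
    """
    amap = np.asarray(green_activity_map, dtype=float)
    if amap.ndim != 2:
        raise ParameterError("expected a 2-D activity map")
    if n_max < 1 or min_pixels < 1:
        raise ParameterError("n_max and min_pixels must be >= 1")
    top = float(amap.max())
    floor = float(np.quantile(amap, floor_quantile))
    if not np.isfinite(top) or top <= floor:
        return RoiSet([], np.array([]), min_pixels, n_max, status="empty")

    thresholds = np.linspace(top, floor, n_threshold_steps, endpoint=False)[1:]
    best_masks: list[np.ndarray] = []
    best_thr = float("nan")
    best_at_cap = False
    for thr in thresholds:
        masks = _components(amap >= thr, min_pixels)
        at_cap = len(masks) >= n_max
        better = (
            (at_cap and not best_at_cap)
            or (at_cap and best_at_cap)  # lower threshold, still at the cap
            or (not best_at_cap and len(masks) >= len(best_masks))
        )
        if better and masks:
            best_masks, best_thr, best_at_cap = masks, float(thr), at_cap
        if best_at_cap and not at_cap:
            # the count fell back below the cap (regions merging into noise):
            # keep the lowest threshold that still held the cap
            break
    if not best_masks:
        return RoiSet([], np.array([]), min_pixels, n_max, status="empty",
                      threshold=best_thr)

    def _key(mask: np.ndarray):
        peak = float(amap[mask].max())
        cy, cx = np.argwhere(mask).mean(axis=0)
        return (-peak, float(cy), float(cx))

    ordered = sorted(best_masks, key=_key)[:n_max]
    activity = np.array([float(amap[m].max()) for m in ordered])
    status = "ok" if len(ordered) == n_max else f"short:{len(ordered)}"
    return RoiSet(ordered, activity, min_pixels, n_max, status=status,
                  threshold=best_thr)


def extract_roi_traces(z_stack: np.ndarray, rois: RoiSet) -> np.ndarray:
    """(n_rois, t) mean-over-member-pixel traces, re-standardized per trace."""
    z_stack = np.asarray(z_stack)
    if z_stack.ndim != 3:
        raise ParameterError("expected a 3-D (t, y, x) z-stack")
    traces = np.empty((len(rois), z_stack.shape[0]), dtype=np.float64)
    for k, mask in enumerate(rois.masks):
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise DataError(f"ROI {k} has an empty mask")
        if mask.shape != z_stack.shape[1:]:
            raise DataError(f"ROI {k} mask does not match the FOV")
        t = z_stack[:, mask].mean(axis=1)
        sd = t.std(ddof=0)
        if sd == 0:
            raise DataError(f"ROI {k} trace is constant")
        traces[k] = (t - t.mean()) / sd
    return traces


# --------------------------------------------------------------------------
# traces, peaks, frequencies
# --------------------------------------------------------------------------


def bandpass_trace(
    trace: np.ndarray,
    frame_period_ms: float,
    min_event_ms: float = 150.0,
    max_event_ms: float = 2000.0,
) -> np.ndarray:
    """Zero-phase ideal band-pass keeping oscillation periods within
    [min_event_ms, max_event_ms] (blocker analyses use [500 ms, 10 s])."""
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1:
        raise ParameterError("expected a 1-D trace")
    if frame_period_ms <= 0 or min_event_ms <= 0 or max_event_ms <= min_event_ms:
        raise ParameterError("invalid band definition")
    n = len(trace)
    duration_ms = n * frame_period_ms
    if duration_ms <= max_event_ms:
        raise ParameterError("trace shorter than the longest pass-band period")
    freqs = np.fft.rfftfreq(n, d=frame_period_ms / 1000.0)
    lo, hi = 1000.0 / max_event_ms, 1000.0 / min_event_ms
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        raise ParameterError("pass band contains no frequency bins at this sampling")
    spec = np.fft.rfft(trace)
    spec[~band] = 0.0
    return np.fft.irfft(spec, n)


def detect_peaks(
    filtered_trace: np.ndarray,
    frame_period_ms: float,
    amp_threshold_z: float = 2.0,
    min_fwhm_ms: float = 250.0,
    restandardize: bool = True,
) -> PeakTrain:
    """Local maxima above the amplitude threshold whose full width at half
    maximum exceeds ``min_fwhm_ms``.

    The band-pass attenuates overall variance, so by default the filtered
    trace is re-standardized before thresholding.  The scale is noise-robust
    (median / 1.4826*MAD, which equals the SD for Gaussian noise): a plain
    SD would be inflated by the events themselves and cap busy traces below
    the threshold regardless of their true signal-to-noise.  Traces whose
    MAD is zero (e.g. analytic pulses on an exactly flat baseline) are taken
    as already standardized.

    Widths are measured at half the peak's topographic prominence
    (:func:`scipy.signal.peak_widths` with ``rel_height=0.5``); for an
    isolated pulse on a flat baseline this is exactly the classical FWHM,
    and on an oscillating filtered baseline it remains well defined.
    """
    trace = np.asarray(filtered_trace, dtype=np.float64)
    if trace.ndim != 1 or trace.size < 3:
        raise ParameterError("expected a 1-D trace with at least 3 samples")
    if frame_period_ms <= 0:
        raise ParameterError("frame period must be positive")
    if restandardize:
        med = np.median(trace)
        mad = np.median(np.abs(trace - med))
        if mad > 0:
            trace = (trace - med) / (1.4826 * mad)
    peaks, _ = signal.find_peaks(trace, height=amp_threshold_z)
    peaks = peaks[trace[peaks] > amp_threshold_z]
    frames, amps, widths = [], [], []
    if peaks.size:
        width_frames = signal.peak_widths(trace, peaks, rel_height=0.5)[0]
        for p, wf in zip(peaks, width_frames):
            w = float(wf * frame_period_ms)
            if w > min_fwhm_ms:
                frames.append(int(p))
                amps.append(float(trace[p]))
                widths.append(w)
    return PeakTrain(
        peak_frames=np.array(frames, dtype=int),
        peak_amplitudes_z=np.array(amps),
        fwhm_ms=np.array(widths),
        frame_period_ms=frame_period_ms,
    )


def roi_response(
    train: PeakTrain,
    baseline_window: tuple[float, float],
    stim_window: tuple[float, float],
    min_increase: float = 0.25,
) -> tuple[bool, float, float]:
    """(responsive, baseline_hz, stim_hz).

    Responsive iff the stimulation-window peak frequency exceeds the baseline
    frequency by more than ``min_increase`` (fractional); a silent baseline
    with at least one stimulation peak counts as responsive.
    """
    if min_increase < 0:
        raise ParameterError("min_increase must be non-negative")
    base = train.frequency_hz(baseline_window)
    stim = train.frequency_hz(stim_window)
    if base == 0.0:
        return stim > 0.0, base, stim
    return stim > base * (1.0 + min_increase), base, stim


# --------------------------------------------------------------------------
# cell-level rules
# --------------------------------------------------------------------------


def _paired_wilcoxon(post: np.ndarray, pre: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value; 1.0 when every pair is tied."""
    diffs = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(post, pre, alternative="two-sided").pvalue)


def classify_invivo_cell(
    trains: list[PeakTrain],
    roi_masks: list,
    fov_area_px: int,
    stim_onset_s: float,
    total_duration_s: float,
    area_threshold: float = 0.03,
    alpha: float = 0.05,
    effect_window_s: float = 10.0,
    min_increase: float = 0.25,
    min_rois: int = 6,
    effect_window_step_s: float = 5.0,
) -> InVivoCellResult:
    """Cell-level responder call from per-ROI peak trains.

    The baseline window is the first ``effect_window_s`` before the stimulus;
    the effect window is the post-stimulus ``effect_window_s`` span (sliding
    in ``effect_window_step_s`` steps) that maximizes the mean peak frequency
    across ROIs.  Responder iff responsive ROIs cover at least
    ``area_threshold`` of the FOV AND the paired per-ROI frequency change is
    significant (two-sided Wilcoxon signed-rank, p < alpha) with a positive
    median change.  Fewer than ``min_rois`` ROIs is refused.
    """
    if len(trains) != len(roi_masks):
        raise ParameterError("trains and roi_masks disagree in length")
    if len(trains) < min_rois:
        raise ClassificationRefusedError(
            f"{len(trains)} ROIs available; at least {min_rois} required "
            "for the paired signed-rank test"
        )
    if not (0 < stim_onset_s < total_duration_s):
        raise ParameterError("stimulus onset outside the acquisition")
    if stim_onset_s + effect_window_s > total_duration_s:
        raise ParameterError("no room for an effect window after the stimulus")
    if fov_area_px <= 0:
        raise ParameterError("fov_area_px must be positive")

    base_t1 = min(effect_window_s, stim_onset_s)
    baseline_window = (0.0, base_t1)

    starts = np.arange(
        stim_onset_s, total_duration_s - effect_window_s + 1e-9, effect_window_step_s
    )
    best_start, best_mean = float(starts[0]), -1.0
    for s in starts:
        window = (float(s), float(s + effect_window_s))
        mean_f = float(np.mean([tr.frequency_hz(window) for tr in trains]))
        if mean_f > best_mean:
            best_mean, best_start = mean_f, float(s)
    effect_window = (best_start, best_start + effect_window_s)

    flags, base_f, stim_f = [], [], []
    for tr in trains:
        r, b, s = roi_response(tr, baseline_window, effect_window, min_increase)
        flags.append(r)
        base_f.append(b)
        stim_f.append(s)
    flags = np.array(flags, dtype=bool)
    base_f = np.array(base_f)
    stim_f = np.array(stim_f)

    area_px = int(sum(int(np.asarray(m).sum()) for m, f in zip(roi_masks, flags) if f))
    area_fraction = area_px / fov_area_px
    p_value = _paired_wilcoxon(stim_f, base_f)
    median_up = float(np.median(stim_f - base_f)) > 0
    responder = (area_fraction >= area_threshold) and (p_value < alpha) and median_up
    return InVivoCellResult(
        baseline_freqs_hz=base_f,
        stim_freqs_hz=stim_f,
        response_flags=flags,
        area_fraction=float(area_fraction),
        p_value=p_value,
        responder=bool(responder),
        baseline_window_s=baseline_window,
        effect_window_s=effect_window,
        qc_flags={"mean_effect_freq_hz": best_mean},
    )


def hotspot_overlap(
    responsive_rois_a: list,
    responsive_rois_b: list,
    fov_shape: tuple[int, int],
    blur_sigma: float = 1.0,
) -> dict:
    """Cross-acquisition hotspot matching on blurred responsive-ROI masks.

    Each mask is Gaussian-blurred and re-binarized at half its maximum; an
    ROI pair overlaps when their post-blur masks share a pixel.  Returns the
    overlap fraction (overlapping ROIs of the smaller set / its size), the
    pixel map of intersecting regions, and a status ("ok" or "undefined"
    when either set is empty).
    """
    if blur_sigma < 0:
        raise ParameterError("blur_sigma must be non-negative")

    def _blur(mask):
        mask = np.asarray(mask, dtype=float)
        if mask.shape != tuple(fov_shape):
            raise DataError("ROI mask does not match the FOV shape")
        if blur_sigma == 0:
            return mask > 0
        blurred = ndimage.gaussian_filter(mask, blur_sigma)
        return blurred >= blurred.max() / 2.0 if blurred.max() > 0 else mask > 0

    if not responsive_rois_a or not responsive_rois_b:
        return {
            "fraction": None,
            "hotspot_map": np.zeros(fov_shape, dtype=bool),
            "status": "undefined",
            "n_overlapping": 0,
        }
    blurred_a = [_blur(m) for m in responsive_rois_a]
    blurred_b = [_blur(m) for m in responsive_rois_b]
    union_a = np.any(blurred_a, axis=0)
    union_b = np.any(blurred_b, axis=0)
    small, other_union = (
        (blurred_a, union_b) if len(blurred_a) <= len(blurred_b) else (blurred_b, union_a)
    )
    n_overlap = sum(1 for m in small if np.any(m & other_union))
    return {
        "fraction": n_overlap / len(small),
        "hotspot_map": union_a & union_b,
        "status": "ok",
        "n_overlapping": n_overlap,
    }


def compare_blocker_periods(
    freqs_pre_hz: np.ndarray, freqs_post_hz: np.ndarray
) -> dict:
    """Paired two-sided Wilcoxon signed-rank on matched per-ROI peak
    frequencies from two acquisitions (blocker band [500 ms, 10 s])."""
    pre = np.asarray(freqs_pre_hz, dtype=float)
    post = np.asarray(freqs_post_hz, dtype=float)
    if pre.ndim != 1 or pre.shape != post.shape:
        raise PairingError(
            f"cannot pair {pre.shape} pre vs {post.shape} post ROI frequencies"
        )
    if pre.size == 0:
        raise PairingError("no ROI frequencies to compare")
    return {
        "p_value": _paired_wilcoxon(post, pre),
        "mean_pre_hz": float(pre.mean()),
        "mean_post_hz": float(post.mean()),
        "n_rois": int(pre.size),
    }


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def run_invivo_pipeline(
    green: np.ndarray,
    red: np.ndarray,
    frame_period_ms: float,
    stim_onset_s: float,
    smooth_sigma: float = 3.0,
    contrast_threshold: float = 1.2,
    max_shift_px: float = 5.0,
    n_max_rois: int = 50,
    min_roi_pixels: int = 5,
    activity_metric: str = "robust",
    min_event_ms: float = 150.0,
    max_event_ms: float = 2000.0,
    amp_threshold_z: float = 2.0,
    min_fwhm_ms: float = 250.0,
    min_increase: float = 0.25,
    area_threshold: float = 0.03,
    alpha: float = 0.05,
    effect_window_s: float = 10.0,
) -> dict:
    """Full awake-mouse analysis from raw two-channel stacks.

    Stabilizes on the red channel, z-scores the kept green frames per pixel,
    segments ROIs, detects band-limited peaks, and applies the cell-level
    responder rules.  Frequencies are computed on kept time; the stimulus
    onset is mapped onto the kept-frame timeline.
    """
    motion = estimate_motion(
        red, smooth_sigma, contrast_threshold, max_shift_px
    )
    green_stab, index_map = apply_stabilization(green, motion)
    z, _ = zscore_stack(green_stab)
    amap = activity_map(z, metric=activity_metric)
    rois = segment_rois(amap, n_max=n_max_rois, min_pixels=min_roi_pixels)
    if len(rois) == 0:
        raise DataError("no ROIs could be segmented from the activity map")
    traces = extract_roi_traces(z, rois)
    trains = []
    for tr in traces:
        filt = bandpass_trace(tr, frame_period_ms, min_event_ms, max_event_ms)
        trains.append(detect_peaks(filt, frame_period_ms, amp_threshold_z, min_fwhm_ms))

    dt_s = frame_period_ms / 1000.0
    stim_frame = int(round(stim_onset_s / dt_s))
    # kept-time position of the stimulus = number of kept frames before it
    stim_onset_kept_s = float(np.count_nonzero(index_map < stim_frame) * dt_s)
    total_kept_s = len(index_map) * dt_s
    result = classify_invivo_cell(
        trains,
        rois.masks,
        fov_area_px=int(np.prod(green.shape[1:])),
        stim_onset_s=stim_onset_kept_s,
        total_duration_s=total_kept_s,
        area_threshold=area_threshold,
        alpha=alpha,
        effect_window_s=effect_window_s,
        min_increase=min_increase,
    )
    return {
        "result": result,
        "motion": motion,
        "rois": rois,
        "activity_map": amap,
        "traces": traces,
        "trains": trains,
        "index_map": index_map,
    }
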