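"""Shared denoising and normalisation front-end.

Both analysis pipelines consume z-scored stacks produced by the fixed chain

    normalise -> non-local-means denoise -> spatiotemporal Gaussian smooth
              -> dF/F0 -> per-pixel z-score

Every step preserves the (t, y, x) shape; each can be disabled through
:class:`PreprocessParams`.  Thresholds downstream ("1z", "2z") are expressed
in the per-pixel standardised units produced by :func:`zscore_stack`, which
uses the population (ddof=0) standard deviation over the whole acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_nl_means

from .errors import DataError, ParameterError

__all__ = [
    "TwoChannelMovie",
    "PreprocessParams",
    "normalize_stack",
    "denoise_nlm",
    "smooth_spatiotemporal",
    "compute_dff",
    "zscore_stack",
    "preprocess_stack",
    "estimate_snr",
]


@dataclass
class TwoChannelMovie:
    """A two-channel 2D+t acquisition.

    green : (t, y, x) glutamate-sensor intensity stack
    red   : (t, y, x) tracer / morphology intensity stack (same shape)
    """

    green: np.ndarray
    red: np.ndarray
    frame_period_ms: float
    pixel_size_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.green.ndim != 3 or self.red.ndim != 3:
            raise DataError("movie stacks must be 3-D (t, y, x)")
        if self.green.shape != self.red.shape:
            raise DataError(
                f"channel shapes differ: green {self.green.shape} vs red {self.red.shape}"
            )
        if self.frame_period_ms <= 0:
            raise ParameterError("frame_period_ms must be positive")
        for name, stack in (("green", self.green), ("red", self.red)):
            if not np.all(np.isfinite(stack)):
                raise DataError(f"{name} channel contains non-finite values")
            if np.any(stack < 0):
                raise DataError(f"{name} channel contains negative intensities")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def fov_shape(self) -> tuple[int, int]:
        return self.green.shape[1:]

    @property
    def frame_rate_hz(self) -> float:
        return 1000.0 / self.frame_period_ms


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the shared preprocessing chain.

    The non-local-means step runs frame by frame with patch size ``s``,
    patch search distance ``W`` and smoothing factor ``h`` (in units of the
    normalised intensity scale).  The Gaussian step is separable in
    (t, y, x) with the given sigmas (frames / pixels).
    """

    nlm_patch_size: int = 2
    nlm_patch_distance: int = 4
    nlm_h: float = 0.8
    gaussian_sigma_x: float = 0.5
    gaussian_sigma_y: float = 0.5
    gaussian_sigma_t: float = 0.5
    enable_normalize: bool = True
    enable_nlm: bool = True
    enable_smooth: bool = True

    def __post_init__(self):
        if self.enable_nlm:
            if self.nlm_patch_size <= 0 or self.nlm_patch_distance <= 0:
                raise ParameterError("NLM patch size and distance must be positive")
            if self.nlm_h <= 0:
                raise ParameterError("NLM smoothing factor h must be positive")
        if self.enable_smooth:
            if min(self.gaussian_sigma_x, self.gaussian_sigma_y, self.gaussian_sigma_t) <= 0:
                raise ParameterError("Gaussian sigmas must be positive when smoothing is enabled")


class DffResult(NamedTuple):
    dff: np.ndarray
    invalid_mask: np.ndarray  # (y, x) pixels with near-zero baseline, set to 0


class ZScoreResult(NamedTuple):
    z: np.ndarray
    constant_mask: np.ndarray  # (y, x) zero-variance pixels, set to 0


class PreprocessResult(NamedTuple):
    z: np.ndarray
    invalid_mask: np.ndarray
    constant_mask: np.ndarray


def _check_stack(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ParameterError("expected a 3-D (t, y, x) stack")
    return stack


def normalize_stack(stack: np.ndarray) -> np.ndarray:
    """Min-max normalise a stack to [0, 1] using its global range.

    Per-pixel z-scoring is invariant to this affine rescaling, so it only
    serves to put the NLM smoothing factor on a fixed intensity scale.
    """
    stack = _check_stack(stack).astype(np.float32, copy=True)
    lo = float(stack.min())
    hi = float(stack.max())
    if hi > lo:
        stack -= lo
        stack /= hi - lo
    else:
        stack[:] = 0.0
    return stack


def denoise_nlm(stack: np.ndarray, params: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Feature-preserving non-local-means filter applied frame by frame."""
    stack = _check_stack(stack)
    h, w = stack.shape[1:]
    window = 2 * params.nlm_patch_distance + params.nlm_patch_size
    if window > min(h, w):
        raise ParameterError(
            f"NLM search window ({window} px) exceeds the frame size ({h}x{w})"
        )
    out = np.empty_like(stack, dtype=np.float32)
    for i in range(stack.shape[0]):
        out[i] = denoise_nl_means(
            stack[i].astype(np.float32),
            patch_size=params.nlm_patch_size,
            patch_distance=params.nlm_patch_distance,
            h=params.nlm_h,
            fast_mode=True,
        )
    return out


def smooth_spatiotemporal(
    stack: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> np.ndarray:
    """Separable Gaussian smoothing in (t, y, x) with reflecting boundaries."""
    stack = _check_stack(stack)
    if params.gaussian_sigma_t > 0 and stack.shape[0] < 3:
        raise ParameterError("temporal smoothing requires at least 3 frames")
    sigma = (params.gaussian_sigma_t, params.gaussian_sigma_y, params.gaussian_sigma_x)
    return ndimage.gaussian_filter(
        stack.astype(np.float32), sigma=sigma, mode="reflect"
    )


def compute_dff(stack: np.ndarray, eps: float = 1e-6) -> DffResult:
    """Relative fluorescence change (F - F0)/F0 with F0 the per-pixel temporal mean.

    Pixels whose baseline is <= ``eps`` are reported in ``invalid_mask`` and
    set to zero rather than producing infinities.
    """
    stack = _check_stack(stack)
    f0 = stack.mean(axis=0, dtype=np.float64)
    invalid = f0 <= eps
    safe_f0 = np.where(invalid, 1.0, f0)
    dff = (stack - f0[None]) / safe_f0[None]
    dff = dff.astype(np.float32)
    if invalid.any():
        dff[:, invalid] = 0.0
    return DffResult(dff, invalid)


def zscore_stack(stack: np.ndarray) -> ZScoreResult:
    """Per-pixel temporal standardisation over the whole acquisition.

    Uses whole-acquisition statistics and the population SD convention
    (ddof=0).  Zero-variance pixels are reported and set to zero.
    """
    stack = _check_stack(stack)
    mean = stack.mean(axis=0, dtype=np.float64)
    sd = stack.std(axis=0, ddof=0, dtype=np.float64)
    # an exactly constant pixel can still yield a tiny nonzero SD after the
    # float32 cast (the temporal mean rounds), so detect constancy directly
    constant = stack.max(axis=0) == stack.min(axis=0)
    safe_sd = np.where(constant | (sd == 0), 1.0, sd)
    z = ((stack - mean[None]) / safe_sd[None]).astype(np.float32)
    if constant.any():
        z[:, constant] = 0.0
    return ZScoreResult(z, constant)


def preprocess_stack(
    stack: np.ndarray, params: PreprocessParams = PreprocessParams()
) -> PreprocessResult:
    """Run the full chain normalise -> NLM -> smooth -> dF/F0 -> z-score."""
    stack = _check_stack(stack)
    work = normalize_stack(stack) if params.enable_normalize else stack.astype(np.float32)
    if params.enable_nlm:
        work = denoise_nlm(work, params)
    if params.enable_smooth:
        work = smooth_spatiotemporal(work, params)
    dff, invalid = compute_dff(work)
    z, constant = zscore_stack(dff)
    return PreprocessResult(z, invalid, constant)


def estimate_snr(
    stack: np.ndarray, event_mask: np.ndarray, baseline_frames: np.ndarray
) -> float:
    """Signal-to-noise ratio: mean event peak amplitude over baseline SD.

    event_mask : boolean (t, y, x) samples belonging to known events.
    baseline_frames : boolean (t,) frames declared quiescent.

    The event peak per pixel is the maximum over that pixel's event samples,
    referenced to the mean of the baseline samples at the event pixels.
    """
    stack = _check_stack(stack)
    event_mask = np.asarray(event_mask, dtype=bool)
    baseline_frames = np.asarray(baseline_frames, dtype=bool)
    if event_mask.shape != stack.shape:
        raise ParameterError("event_mask must match the stack shape")
    if baseline_frames.shape != (stack.shape[0],) or not baseline_frames.any():
        raise ParameterError("baseline window is empty or mis-shaped")
    if not event_mask.any():
        raise ParameterError("event mask selects no samples")
    pixels = event_mask.any(axis=0)
    base = stack[baseline_frames][:, pixels].astype(np.float64)
    mu, sd = base.mean(), base.std(ddof=0)
    if sd == 0:
        raise ParameterError("baseline samples have zero variance")
    masked = np.where(event_mask, stack, -np.inf)
    peaks = masked.max(axis=0)[pixels]
    return float((peaks.mean() - mu) / sd)
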