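"""Kinetic measurements on single-event fluorescence traces."""

from __future__ import annotations

import numpy as np

from .errors import DataError, ParameterError

__all__ = ["measure_rise_time_ms", "measure_decay_tau_ms"]


def _check_trace(trace: np.ndarray) -> np.ndarray:
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or trace.size < 3:
        raise ParameterError("expected a 1-D trace with at least 3 samples")
    if not np.all(np.isfinite(trace)):
        raise DataError("trace contains non-finite values")
    return trace


def _crossing_time(trace: np.ndarray, start: int, stop: int, level: float,
                   dt: float, rising: bool) -> float:
    """Linearly interpolated time at which the trace crosses ``level``.

    Scans ``start..stop`` forward for a rising crossing or backward from the
    peak for a falling reference; here only the rising case is needed, the
    flag is kept for symmetry with the decay fit.
    """
    rng = range(start, stop) if rising else range(stop - 1, start - 1, -1)
    for i in rng:
        a, b = trace[i], trace[i + 1]
        crossed = (a < level <= b) if rising else (b < level <= a)
        if crossed:
            frac = (level - a) / (b - a)
            return (i + frac) * dt
    raise DataError(f"trace never crosses the {level:.3g} level")


def measure_rise_time_ms(trace: np.ndarray, frame_period_ms: float,
                         baseline: float | None = None) -> float:
    """10-90% rise time of a single-event trace, in ms.

    The event amplitude is peak minus baseline (default: the trace minimum
    before the peak).  Crossing times of the 10% and 90% levels on the
    rising flank are located by linear interpolation between samples.
    """
    trace = _check_trace(trace)
    if frame_period_ms <= 0:
        raise ParameterError("frame period must be positive")
    peak_idx = int(np.argmax(trace))
    if peak_idx == 0:
        raise DataError("trace peaks at the first sample; no rising flank")
    base = float(trace[:peak_idx].min()) if baseline is None else float(baseline)
    amp = trace[peak_idx] - base
    if amp <= 0:
        raise DataError("event amplitude is non-positive")
    lo, hi = base + 0.1 * amp, base + 0.9 * amp
    t10 = _crossing_time(trace, 0, peak_idx, lo, frame_period_ms, rising=True)
    t90 = _crossing_time(trace, 0, peak_idx, hi, frame_period_ms, rising=True)
    if t90 <= t10:
        raise DataError("degenerate rising flank")
    return t90 - t10


def measure_decay_tau_ms(trace: np.ndarray, frame_period_ms: float,
                         baseline: float | None = None,
                         fit_floor: float = 0.05) -> float:
    """Mono-exponential decay constant from a log-linear fit of the falling
    flank, in ms.

    Samples from the peak down to ``fit_floor`` of the amplitude enter the
    fit; returns the negative inverse slope of log(F - baseline) vs t.
    """
    trace = _check_trace(trace)
    if frame_period_ms <= 0:
        raise ParameterError("frame period must be positive")
    if not (0.0 < fit_floor < 1.0):
        raise ParameterError("fit_floor must be in (0, 1)")
    peak_idx = int(np.argmax(trace))
    base = float(trace.min()) if baseline is None else float(baseline)
    amp = trace[peak_idx] - base
    if amp <= 0:
        raise DataError("event amplitude is non-positive")
    tail = trace[peak_idx:] - base
    usable = tail > fit_floor * amp
    # stop at the first sub-floor sample so late noise does not enter the fit
    cutoff = int(np.argmin(usable)) if not usable.all() else len(tail)
    if cutoff < 3:
        raise DataError("too few samples on the decay flank for a fit")
    y = np.log(tail[:cutoff])
    t = frame_period_ms * np.arange(cutoff)
    slope = np.polyfit(t, y, 1)[0]
    if slope >= 0:
        raise DataError("decay flank is not decreasing")
    return -1.0 / slope
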