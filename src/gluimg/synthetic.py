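"""Synthetic two-photon glutamate-sensor movies with known ground truth.

The generator emulates the acquisitions the analysis pipelines were designed
for: 33 Hz (30 ms frame period) two-channel movies in which the green channel
carries a surface glutamate sensor and the red channel either a co-puffed
tracer dye (slice experiments) or a static morphology stain (awake-mouse
experiments).

Slice ("in situ") movies contain six tracer-visible puffs 20 s apart over a
120 s acquisition, with sub-second glutamate events (~100 ms rise, 450 ms
sensor off-rate) confined to grid-aligned release hotspots, plus a companion
acquisition in which bath glutamate drives the whole sensor-expressing field
(the positive control).  Awake-mouse ("in vivo") movies carry asynchronous
local events at compact active regions whose rate can step up after a
stimulus, optional slow global waves, and frame-to-frame motion.

Every movie comes with a :class:`GroundTruth` record so each downstream
analysis stage can be scored against what was injected.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from .errors import ParameterError
from .preprocess import TwoChannelMovie

__all__ = [
    "MovieSpec",
    "StimulusProtocol",
    "EventKinetics",
    "HotspotConfig",
    "ActivityConfig",
    "MotionConfig",
    "GroundTruth",
    "InSituSimulation",
    "make_event_kernel",
    "generate_insitu_movie",
    "generate_invivo_movie",
    "default_insitu_spec",
    "default_invivo_spec",
    "write_fixture_set",
    "SCENARIOS",
]


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MovieSpec:
    """Geometry, timing and noise of one acquisition."""

    width_px: int = 128
    height_px: int = 128
    pixel_size_um: float = 0.293
    frame_period_ms: float = 30.0
    duration_s: float = 120.0
    baseline_green: float = 100.0
    baseline_red: float = 100.0
    gaussian_sd: float = 8.0
    poisson_scale: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.width_px < 16 or self.height_px < 16:
            raise ParameterError("FOV must be at least 16x16 pixels")
        if self.frame_period_ms <= 0 or self.duration_s <= 0:
            raise ParameterError("frame period and duration must be positive")
        if self.gaussian_sd < 0 or self.poisson_scale < 0:
            raise ParameterError("noise parameters must be non-negative")

    @property
    def n_frames(self) -> int:
        return round(self.duration_s * 1000.0 / self.frame_period_ms)

    @property
    def noise_ref(self) -> float:
        """Count scale against which ``amplitude_z`` is expressed.

        Equal to the Gaussian read-noise SD; 1.0 for noiseless movies so
        event amplitudes stay well defined.
        """
        return self.gaussian_sd if self.gaussian_sd > 0 else 1.0


def default_insitu_spec(**overrides) -> MovieSpec:
    """Slice acquisition defaults: 128x128 px, 0.293 um/px, 120 s at 30 ms."""
    return MovieSpec(**overrides)


def default_invivo_spec(**overrides) -> MovieSpec:
    """Awake-mouse acquisition defaults: 128x128 px, 1.18 um/px, 60 s at 30 ms."""
    kwargs = dict(pixel_size_um=1.18, duration_s=60.0)
    kwargs.update(overrides)
    return MovieSpec(**kwargs)


@dataclass(frozen=True)
class StimulusProtocol:
    """Repeated-puff stimulation visible as red tracer transients."""

    n_puffs: int = 6
    interval_s: float = 20.0
    puff_duration_ms: float = 10.0
    first_puff_s: float = 8.0
    drug_label: str = "CNO"
    red_rise_amplitude: float = 80.0
    red_decay_s: float = 2.0

    def __post_init__(self):
        if self.n_puffs < 1:
            raise ParameterError("a protocol needs at least one puff")
        if self.interval_s <= 0 or self.first_puff_s < 0:
            raise ParameterError("puff timing must be positive")

    def onset_times_s(self) -> np.ndarray:
        return self.first_puff_s + self.interval_s * np.arange(self.n_puffs)

    def onset_frames(self, frame_period_ms: float) -> np.ndarray:
        return np.round(self.onset_times_s() * 1000.0 / frame_period_ms).astype(int)

    def check_fits(self, spec: MovieSpec) -> None:
        last = self.first_puff_s + (self.n_puffs - 1) * self.interval_s
        if last + 1.0 >= spec.duration_s:
            raise ParameterError(
                f"protocol overflows the acquisition: last puff at {last:.1f} s "
                f"+ 1 s window vs duration {spec.duration_s:.1f} s"
            )


@dataclass(frozen=True)
class EventKinetics:
    """Temporal shape of a single glutamate event.

    ``rise_ms`` is the 10-90% rise time of the (linear-ramp) rising phase;
    ``decay_ms`` is the mono-exponential decay constant set by the sensor
    off-rate.  ``amplitude_z`` is the event peak in units of the movie's
    read-noise SD.
    """

    rise_ms: float = 100.0
    decay_ms: float = 450.0
    amplitude_z: float = 4.0

    def __post_init__(self):
        if self.rise_ms <= 0 or self.decay_ms <= 0:
            raise ParameterError("rise and decay times must be positive")
        if self.amplitude_z <= 0:
            raise ParameterError("event amplitude must be positive")


@dataclass(frozen=True)
class HotspotConfig:
    """Placement and responsiveness of release hotspots in slice movies.

    Hotspots are connected blobs of grid-aligned ``grid_cell_px`` squares so
    that ground truth maps one-to-one onto the analysis grid.  A responder
    cell carries ``n_hotspots`` blobs of ``cells_per_hotspot`` grid cells,
    each firing per puff epoch with ``response_probability``; a non-responder
    carries a single, rarely firing one-cell site (small residual signal).
    """

    n_hotspots: int = 4
    cells_per_hotspot: int = 9
    response_probability: float = 0.9
    responder: bool = True
    responder_fraction: float = 0.05
    grid_cell_px: int = 4
    lglut_fraction: float = 1.0
    lglut_amplitude_z: float = 6.0
    lglut_response_probability: float = 1.0
    event_latency_frames: int = 1

    def __post_init__(self):
        if not (0.0 <= self.response_probability <= 1.0):
            raise ParameterError("response_probability must be in [0, 1]")
        if not (0.0 < self.lglut_fraction <= 1.0):
            raise ParameterError("lglut_fraction must be in (0, 1]")
        if self.grid_cell_px < 1 or self.cells_per_hotspot < 1:
            raise ParameterError("grid cell size and hotspot size must be >= 1")


@dataclass(frozen=True)
class ActivityConfig:
    """Spontaneous / evoked activity structure of awake-mouse movies."""

    n_regions: int = 60
    region_pixels: int = 16
    baseline_rate_hz: float = 0.2
    stim_rate_factor: float = 2.0
    slow_wave_amplitude_z: float = 0.0
    slow_wave_period_s: float = 5.0

    def __post_init__(self):
        if self.n_regions < 0 or self.region_pixels < 1:
            raise ParameterError("invalid active-region configuration")
        if self.baseline_rate_hz < 0 or self.stim_rate_factor < 0:
            raise ParameterError("event rates must be non-negative")
        if self.slow_wave_period_s <= 2.0:
            raise ParameterError("slow waves must have period > 2 s")


@dataclass(frozen=True)
class MotionConfig:
    """Frame-to-frame displacement of awake-mouse movies."""

    jitter_sd_px: float = 0.3
    n_large_motion_frames: int = 0
    large_shift_px: float = 8.0

    def __post_init__(self):
        if self.jitter_sd_px < 0 or self.n_large_motion_frames < 0:
            raise ParameterError("invalid motion configuration")


@dataclass
class GroundTruth:
    """Everything that was injected into a synthetic movie."""

    puff_onset_frames: dict = field(default_factory=dict)  # label -> frame array
    hotspot_masks: list = field(default_factory=list)  # (y, x) boolean pixel masks
    hotspot_cells: list = field(default_factory=list)  # per hotspot: list of (row, col) grid cells
    hotspot_centers: list = field(default_factory=list)  # (y, x) pixel centres
    event_table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["hotspot_id", "epoch_id", "onset_frame", "amplitude", "protocol"]
        )
    )
    lglut_mask: np.ndarray | None = None
    responder: bool = False
    responding_fraction: float = 0.0
    motion_trace: np.ndarray | None = None  # (t, 2) injected (dy, dx)
    large_motion_frames: np.ndarray | None = None
    region_masks: list = field(default_factory=list)  # in vivo active regions
    region_centers: list = field(default_factory=list)
    region_event_frames: list = field(default_factory=list)  # per region event onset frames
    stim_onset_frame: int | None = None


@dataclass
class InSituSimulation:
    """A drug acquisition, its positive-control acquisition and their truth."""

    drug: TwoChannelMovie
    lglut: TwoChannelMovie | None
    truth: GroundTruth


# --------------------------------------------------------------------------
# event kernel
# --------------------------------------------------------------------------


def make_event_kernel(kinetics: EventKinetics, frame_period_ms: float) -> np.ndarray:
    """Discrete unit-peak event kernel: linear ramp then exponential decay.

    The ramp duration is ``rise_ms / 0.8`` so that the 10-90% rise time of
    the continuous shape equals ``rise_ms``; the decay is mono-exponential
    with time constant ``decay_ms`` and the kernel extends over at least five
    decay constants.  The sample at the ramp/decay junction is exactly 1.0,
    and the k-th sample after it equals exp(-k*dt/decay_ms).
    """
    if frame_period_ms <= 0:
        raise ParameterError("frame period must be positive")
    dt = frame_period_ms
    ramp_total = kinetics.rise_ms / 0.8
    n_rise = math.ceil(ramp_total / dt)
    rise_offsets = dt * np.arange(n_rise, 0, -1)
    rise = np.clip(1.0 - rise_offsets / ramp_total, 0.0, None)
    n_decay = math.ceil(5.0 * kinetics.decay_ms / dt)
    decay = np.exp(-dt * np.arange(1, n_decay + 1) / kinetics.decay_ms)
    return np.concatenate([rise, [1.0], decay])


def kernel_peak_index(kinetics: EventKinetics, frame_period_ms: float) -> int:
    """Index of the unit-amplitude sample within :func:`make_event_kernel` output."""
    return math.ceil((kinetics.rise_ms / 0.8) / frame_period_ms)


def _add_event(stack: np.ndarray, mask: np.ndarray, onset: int, kernel: np.ndarray, amp: float):
    """Add ``amp * kernel`` starting at ``onset`` (may be negative) to all
    pixels in ``mask``; out-of-range samples are clipped."""
    n = stack.shape[0]
    start = max(0, onset)
    stop = min(n, onset + len(kernel))
    if stop <= start:
        return
    seg = (amp * kernel[start - onset : stop - onset]).astype(np.float32)
    stack[start:stop, mask] += seg[:, None]


def _apply_noise(stack: np.ndarray, spec: MovieSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.poisson_scale > 0:
        stack = rng.poisson(np.clip(stack, 0, None) * spec.poisson_scale).astype(
            np.float32
        ) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        stack = stack + spec.gaussian_sd * rng.standard_normal(stack.shape, dtype=np.float32)
    return np.clip(stack, 0.0, None)


# --------------------------------------------------------------------------
# in situ (slice) movies
# --------------------------------------------------------------------------


def _blob_cells(n: int) -> list[tuple[int, int]]:
    """Row-major fill of a near-square block: n connected grid-cell offsets."""
    side = math.ceil(math.sqrt(n))
    cells = [(r, c) for r in range(side) for c in range(side)]
    return cells[:n]


def _place_hotspots(
    cfg: HotspotConfig, n_rows: int, n_cols: int, rng: np.random.Generator,
    n_hotspots: int, cells_per_hotspot: int,
) -> list[list[tuple[int, int]]]:
    """Choose non-overlapping grid-aligned blobs; returns grid-cell lists."""
    offsets = _blob_cells(cells_per_hotspot)
    side = max(max(r, c) for r, c in offsets) + 1
    taken = np.zeros((n_rows, n_cols), dtype=bool)
    hotspots: list[list[tuple[int, int]]] = []
    attempts = 0
    while len(hotspots) < n_hotspots:
        attempts += 1
        if attempts > 2000:
            raise ParameterError("could not place the requested hotspots in the FOV")
        r0 = int(rng.integers(0, n_rows - side + 1))
        c0 = int(rng.integers(0, n_cols - side + 1))
        cells = [(r0 + r, c0 + c) for r, c in offsets]
        # a 1-cell moat keeps hotspots from touching, so truth components
        # match labelled components one-to-one
        region = taken[max(0, r0 - 1):r0 + side + 1, max(0, c0 - 1):c0 + side + 1]
        if region.any():
            continue
        for r, c in cells:
            taken[r, c] = True
        hotspots.append(cells)
    return hotspots


def _cells_to_pixel_mask(cells, cell_px: int, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r, c in cells:
        mask[r * cell_px:(r + 1) * cell_px, c * cell_px:(c + 1) * cell_px] = True
    return mask


def _red_channel(
    spec: MovieSpec, protocol: StimulusProtocol, rng: np.random.Generator
) -> np.ndarray:
    """Baseline + per-puff step-and-decay tracer transient, graded from the
    pipette (left) edge of the FOV, plus noise."""
    n, h, w = spec.n_frames, spec.height_px, spec.width_px
    dt_s = spec.frame_period_ms / 1000.0
    t = np.arange(n) * dt_s
    temporal = np.zeros(n, dtype=np.float32)
    for onset in protocol.onset_times_s():
        after = t >= onset
        temporal[after] += np.exp(-(t[after] - onset) / protocol.red_decay_s).astype(
            np.float32
        )
    profile = np.linspace(1.0, 0.6, w, dtype=np.float32)[None, :].repeat(h, axis=0)
    red = spec.baseline_red + protocol.red_rise_amplitude * temporal[:, None, None] * profile[None]
    return _apply_noise(red.astype(np.float32), spec, rng)


def generate_insitu_movie(
    spec: MovieSpec = MovieSpec(),
    protocol_drug: StimulusProtocol = StimulusProtocol(),
    protocol_lglut: StimulusProtocol | None = StimulusProtocol(drug_label="LGLUT"),
    kinetics: EventKinetics = EventKinetics(),
    hotspot_config: HotspotConfig = HotspotConfig(),
) -> InSituSimulation:
    """Simulate a slice experiment: a drug acquisition plus (optionally) the
    whole-field glutamate positive-control acquisition.

    Returns the two movies and a :class:`GroundTruth` holding hotspot pixel
    masks, the per-(hotspot, epoch) event table, puff onset frames, the
    positive-control mask and the responder flag (true when the hotspot area
    covers at least ``responder_fraction`` of the control-responsive area).
    """
    protocol_drug.check_fits(spec)
    if protocol_lglut is not None:
        protocol_lglut.check_fits(spec)
    rng = np.random.default_rng(spec.seed)
    cfg = hotspot_config
    n, h, w = spec.n_frames, spec.height_px, spec.width_px
    cell = cfg.grid_cell_px
    n_rows, n_cols = h // cell, w // cell
    kernel = make_event_kernel(kinetics, spec.frame_period_ms)
    amp_counts = kinetics.amplitude_z * spec.noise_ref

    if cfg.responder:
        n_hot, cells_per = cfg.n_hotspots, cfg.cells_per_hotspot
        p_resp = cfg.response_probability
    else:
        n_hot, cells_per = (1, 1)
        p_resp = min(cfg.response_probability, 0.3)

    hotspot_cells = (
        _place_hotspots(cfg, n_rows, n_cols, rng, n_hot, cells_per) if n_hot else []
    )
    hotspot_masks = [_cells_to_pixel_mask(c, cell, (h, w)) for c in hotspot_cells]
    hotspot_centers = [
        tuple(np.argwhere(m).mean(axis=0)) for m in hotspot_masks
    ]

    # positive-control mask: central disk covering lglut_fraction of the FOV,
    # snapped to the grid
    if cfg.lglut_fraction >= 1.0:
        lglut_mask = np.ones((h, w), dtype=bool)
    else:
        yy, xx = np.mgrid[0:n_rows, 0:n_cols]
        cy, cx = (n_rows - 1) / 2, (n_cols - 1) / 2
        radius = math.sqrt(cfg.lglut_fraction * n_rows * n_cols / math.pi)
        cell_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        lglut_mask = np.kron(cell_mask, np.ones((cell, cell), dtype=bool))

    drug_onsets = protocol_drug.onset_frames(spec.frame_period_ms)
    green_drug = np.full((n, h, w), spec.baseline_green, dtype=np.float32)
    events = []
    for hid, mask in enumerate(hotspot_masks):
        for eid, onset in enumerate(drug_onsets):
            if rng.random() <= p_resp:
                ev_onset = int(onset) + cfg.event_latency_frames
                _add_event(green_drug, mask, ev_onset, kernel, amp_counts)
                events.append(
                    dict(
                        hotspot_id=hid,
                        epoch_id=eid,
                        onset_frame=ev_onset,
                        amplitude=amp_counts,
                        protocol=protocol_drug.drug_label,
                    )
                )
    green_drug = _apply_noise(green_drug, spec, rng)
    red_drug = _red_channel(spec, protocol_drug, rng)
    drug_movie = TwoChannelMovie(
        green_drug, red_drug, spec.frame_period_ms, spec.pixel_size_um,
        metadata={"protocol": protocol_drug.drug_label},
    )

    lglut_movie = None
    lglut_onsets = np.array([], dtype=int)
    if protocol_lglut is not None:
        lglut_onsets = protocol_lglut.onset_frames(spec.frame_period_ms)
        green_ctrl = np.full((n, h, w), spec.baseline_green, dtype=np.float32)
        ctrl_amp = cfg.lglut_amplitude_z * spec.noise_ref
        for eid, onset in enumerate(lglut_onsets):
            if rng.random() <= cfg.lglut_response_probability:
                ev_onset = int(onset) + cfg.event_latency_frames
                _add_event(green_ctrl, lglut_mask, ev_onset, kernel, ctrl_amp)
                events.append(
                    dict(
                        hotspot_id=-1,
                        epoch_id=eid,
                        onset_frame=ev_onset,
                        amplitude=ctrl_amp,
                        protocol=protocol_lglut.drug_label,
                    )
                )
        green_ctrl = _apply_noise(green_ctrl, spec, rng)
        red_ctrl = _red_channel(spec, protocol_lglut, rng)
        lglut_movie = TwoChannelMovie(
            green_ctrl, red_ctrl, spec.frame_period_ms, spec.pixel_size_um,
            metadata={"protocol": protocol_lglut.drug_label},
        )

    hotspot_area = int(sum(m.sum() for m in hotspot_masks))
    lglut_area = int(lglut_mask.sum())
    fraction = hotspot_area / lglut_area if lglut_area else 0.0
    truth = GroundTruth(
        puff_onset_frames={
            protocol_drug.drug_label: drug_onsets,
            **(
                {protocol_lglut.drug_label: lglut_onsets}
                if protocol_lglut is not None
                else {}
            ),
        },
        hotspot_masks=hotspot_masks,
        hotspot_cells=hotspot_cells,
        hotspot_centers=hotspot_centers,
        event_table=pd.DataFrame(
            events,
            columns=["hotspot_id", "epoch_id", "onset_frame", "amplitude", "protocol"],
        ),
        lglut_mask=lglut_mask,
        responder=fraction >= cfg.responder_fraction,
        responding_fraction=fraction,
    )
    return InSituSimulation(drug_movie, lglut_movie, truth)


# --------------------------------------------------------------------------
# in vivo (awake mouse) movies
# --------------------------------------------------------------------------


def _place_regions(
    n_regions: int, region_pixels: int, shape: tuple[int, int],
    rng: np.random.Generator, margin: int,
) -> list[np.ndarray]:
    """Non-overlapping compact pixel blobs, kept ``margin`` px from the border."""
    h, w = shape
    side = math.ceil(math.sqrt(region_pixels))
    offsets = _blob_cells(region_pixels)
    taken = np.zeros(shape, dtype=bool)
    masks = []
    attempts = 0
    while len(masks) < n_regions:
        attempts += 1
        if attempts > 20000:
            raise ParameterError("could not place the requested active regions")
        r0 = int(rng.integers(margin, h - margin - side))
        c0 = int(rng.integers(margin, w - margin - side))
        # 2-px moat so neighbouring regions stay separable after smoothing
        if taken[max(0, r0 - 2):r0 + side + 2, max(0, c0 - 2):c0 + side + 2].any():
            continue
        mask = np.zeros(shape, dtype=bool)
        for r, c in offsets:
            mask[r0 + r, c0 + c] = True
        taken |= mask
        masks.append(mask)
    return masks


def _morphology_image(spec: MovieSpec, rng: np.random.Generator) -> np.ndarray:
    """Static astrocyte-like structure for the red channel: bright blobs on a
    dim background, smooth enough to register against."""
    h, w = spec.height_px, spec.width_px
    img = np.zeros((h, w), dtype=np.float32)
    n_blobs = 12
    for _ in range(n_blobs):
        cy = rng.uniform(0.15 * h, 0.85 * h)
        cx = rng.uniform(0.15 * w, 0.85 * w)
        sigma = rng.uniform(2.0, 5.0)
        amp = rng.uniform(0.6, 1.0)
        yy, xx = np.ogrid[0:h, 0:w]
        img += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))).astype(
            np.float32
        )
    img /= max(img.max(), 1e-9)
    return img


def generate_invivo_movie(
    spec: MovieSpec | None = None,
    stimulus: StimulusProtocol | None = None,
    kinetics: EventKinetics = EventKinetics(),
    activity_config: ActivityConfig = ActivityConfig(),
    motion_config: MotionConfig = MotionConfig(),
) -> tuple[TwoChannelMovie, GroundTruth]:
    """Simulate an awake-mouse acquisition.

    The red channel is a static morphology image displaced by the injected
    motion trace; the green channel carries baseline noise, optional global
    slow waves, and local events at the active regions whose rate is
    multiplied by ``stim_rate_factor`` after the stimulus onset (when a
    stimulus protocol is given).
    """
    if spec is None:
        spec = default_invivo_spec()
    act, mot = activity_config, motion_config
    if act.n_regions == 0 and act.baseline_rate_hz > 0:
        raise ParameterError("nonzero event rate requires at least one active region")
    rng = np.random.default_rng(spec.seed)
    n, h, w = spec.n_frames, spec.height_px, spec.width_px
    dt_s = spec.frame_period_ms / 1000.0
    duration = n * dt_s

    margin = int(math.ceil(mot.large_shift_px)) + 2
    regions = _place_regions(act.n_regions, act.region_pixels, (h, w), rng, margin)
    region_centers = [tuple(np.argwhere(m).mean(axis=0)) for m in regions]

    stim_onset_frame = None
    stim_onset_s = None
    if stimulus is not None:
        stim_onset_s = stimulus.first_puff_s
        stim_onset_frame = int(round(stim_onset_s * 1000.0 / spec.frame_period_ms))
        if stim_onset_s >= duration:
            raise ParameterError("stimulus onset beyond the acquisition")

    kernel = make_event_kernel(kinetics, spec.frame_period_ms)
    amp_counts = kinetics.amplitude_z * spec.noise_ref

    clean = np.full((n, h, w), spec.baseline_green, dtype=np.float32)
    if act.slow_wave_amplitude_z > 0:
        t = np.arange(n) * dt_s
        phase = rng.uniform(0, 2 * math.pi)
        wave = act.slow_wave_amplitude_z * spec.noise_ref * np.sin(
            2 * math.pi * t / act.slow_wave_period_s + phase
        )
        clean += wave.astype(np.float32)[:, None, None]

    # burn-in: draw events from one kernel duration before t=0 so activity is
    # stationary at the acquisition start (otherwise the first seconds are
    # systematically quieter than any interior window)
    burn_in_s = len(kernel) * dt_s
    region_event_frames = []
    for mask in regions:
        frames: list[int] = []
        if act.baseline_rate_hz > 0:
            # piecewise-constant-rate Poisson process
            if stim_onset_s is None:
                pieces = [(-burn_in_s, duration, act.baseline_rate_hz)]
            else:
                pieces = [
                    (-burn_in_s, stim_onset_s, act.baseline_rate_hz),
                    (stim_onset_s, duration, act.baseline_rate_hz * act.stim_rate_factor),
                ]
            for t0, t1, rate in pieces:
                if rate <= 0 or t1 <= t0:
                    continue
                count = rng.poisson(rate * (t1 - t0))
                times = np.sort(rng.uniform(t0, t1, count))
                frames.extend(int(math.floor(ft / dt_s)) for ft in times)
        for f in frames:
            _add_event(clean, mask, f, kernel, amp_counts)
        region_event_frames.append(np.array(sorted(frames), dtype=int))

    # motion: small jitter plus a configurable number of large-displacement frames
    shifts = mot.jitter_sd_px * rng.standard_normal((n, 2))
    large_idx = np.array([], dtype=int)
    if mot.n_large_motion_frames > 0:
        large_idx = np.sort(
            rng.choice(np.arange(1, n), size=mot.n_large_motion_frames, replace=False)
        )
        signs = rng.choice([-1.0, 1.0], size=(mot.n_large_motion_frames, 2))
        shifts[large_idx] = mot.large_shift_px * signs

    morph = _morphology_image(spec, rng)
    red_static = spec.baseline_red + 4.0 * spec.noise_ref * 10.0 * morph

    green = np.empty_like(clean)
    red = np.empty((n, h, w), dtype=np.float32)
    any_motion = mot.jitter_sd_px > 0 or mot.n_large_motion_frames > 0
    for i in range(n):
        dy, dx = shifts[i]
        if any_motion and (dy != 0 or dx != 0):
            green[i] = ndimage.shift(clean[i], (dy, dx), order=1, mode="nearest")
            red[i] = ndimage.shift(red_static, (dy, dx), order=1, mode="nearest")
        else:
            green[i] = clean[i]
            red[i] = red_static
    del clean
    green = _apply_noise(green, spec, rng)
    red = _apply_noise(red, spec, rng)

    movie = TwoChannelMovie(
        green, red, spec.frame_period_ms, spec.pixel_size_um,
        metadata={"protocol": stimulus.drug_label if stimulus else "spontaneous"},
    )
    truth = GroundTruth(
        puff_onset_frames=(
            {stimulus.drug_label: np.array([stim_onset_frame])} if stimulus else {}
        ),
        motion_trace=shifts,
        large_motion_frames=large_idx,
        region_masks=regions,
        region_centers=region_centers,
        region_event_frames=region_event_frames,
        stim_onset_frame=stim_onset_frame,
        responder=bool(stimulus is not None and act.stim_rate_factor > 1.0 and regions),
    )
    return movie, truth


# --------------------------------------------------------------------------
# fixture scenarios
# --------------------------------------------------------------------------

SCENARIOS = ("responder", "non-responder", "motion-heavy", "blocker-pre", "blocker-post")


def _scenario_objects(scenario: str, seed: int, spec_overrides: dict | None):
    overrides = dict(spec_overrides or {})
    overrides["seed"] = seed
    if scenario in ("responder", "non-responder"):
        spec = default_insitu_spec(**overrides)
        cfg = HotspotConfig(responder=(scenario == "responder"))
        return "insitu", generate_insitu_movie(spec, hotspot_config=cfg)
    spec = default_invivo_spec(**overrides)
    if scenario == "motion-heavy":
        movie, truth = generate_invivo_movie(
            spec, motion_config=MotionConfig(n_large_motion_frames=5)
        )
    elif scenario == "blocker-pre":
        movie, truth = generate_invivo_movie(
            spec, activity_config=ActivityConfig(slow_wave_amplitude_z=2.0)
        )
    elif scenario == "blocker-post":
        movie, truth = generate_invivo_movie(
            spec, activity_config=ActivityConfig(slow_wave_amplitude_z=0.0)
        )
    else:
        raise ParameterError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    return "invivo", (movie, truth)


def _write_tiff(path: Path, stack: np.ndarray) -> None:
    data = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_fixture_set(
    output_dir, scenario_name: str, seed: int = 0, spec_overrides: dict | None = None
) -> dict:
    """Write TIFF stacks, ground-truth tables and the generating config for a
    named scenario; returns (and writes) a checksummed manifest."""
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write-probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"fixture directory not writable: {out}") from exc

    kind, objects = _scenario_objects(scenario_name, seed, spec_overrides)
    files: list[Path] = []
    truth: GroundTruth
    if kind == "insitu":
        sim: InSituSimulation = objects
        truth = sim.truth
        pairs = [("drug", sim.drug)] + ([("lglut", sim.lglut)] if sim.lglut else [])
        for label, movie in pairs:
            for chan in ("green", "red"):
                p = out / f"{scenario_name}_{label}_{chan}.tif"
                _write_tiff(p, getattr(movie, chan))
                files.append(p)
    else:
        movie, truth = objects
        for chan in ("green", "red"):
            p = out / f"{scenario_name}_{chan}.tif"
            _write_tiff(p, getattr(movie, chan))
            files.append(p)
        motion_path = out / f"{scenario_name}_motion.csv"
        pd.DataFrame(truth.motion_trace, columns=["dy_px", "dx_px"]).to_csv(
            motion_path, index_label="frame"
        )
        files.append(motion_path)

    truth_path = out / f"{scenario_name}_events.csv"
    truth.event_table.to_csv(truth_path, index=False)
    files.append(truth_path)

    summary_path = out / f"{scenario_name}_truth.json"
    summary = {
        "scenario": scenario_name,
        "seed": seed,
        "responder": bool(truth.responder),
        "responding_fraction": float(truth.responding_fraction),
        "n_hotspots": len(truth.hotspot_masks),
        "n_regions": len(truth.region_masks),
        "puff_onset_frames": {
            k: [int(v) for v in arr] for k, arr in truth.puff_onset_frames.items()
        },
        "large_motion_frames": (
            [int(v) for v in truth.large_motion_frames]
            if truth.large_motion_frames is not None
            else []
        ),
    }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    files.append(summary_path)

    config_path = out / f"{scenario_name}_config.yaml"
    config_path.write_text(
        yaml.safe_dump(
            {
                "scenario": scenario_name,
                "seed": seed,
                "spec_overrides": spec_overrides or {},
            },
            sort_keys=True,
        )
    )
    files.append(config_path)

    manifest = {
        "scenario": scenario_name,
        "seed": seed,
        "files": {p.name: _sha256(p) for p in files},
    }
    (out / f"{scenario_name}_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
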