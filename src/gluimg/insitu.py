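"""Slice-experiment analysis: puff-locked epoch scoring on a spatial grid.

The pipeline maps glutamate release sites in a sensor-expressing astrocyte
during repeated agonist puffs:

1. find puff onsets from the co-puffed red tracer (FOV-mean z crossing 1z),
2. tile the FOV with small square grid cells (default 4 px),
3. per grid cell and puff epoch, score a response when the cell's mean
   z-trace reaches >= 2z within 240 ms of onset (2 s for the bath-glutamate
   positive control),
4. keep cells responding reliably (>= 4 of 6 drug puffs, tracer delivery in
   all epochs), intersect the drug map with the positive-control map,
5. label hotspots (8-connected groups of >= 4 cells) and classify the cell
   as a responder when the intersection covers >= 5% of the control-
   responsive area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import (
    DataError,
    MissingControlError,
    OnsetDetectionError,
    ParameterError,
)

__all__ = [
    "GridSpec",
    "EpochSet",
    "ResponseCountMap",
    "FunctionalMap",
    "Hotspot",
    "InSituCellResult",
    "detect_puff_onsets",
    "build_grid",
    "grid_epoch_responses",
    "reliability_maps",
    "intersect_maps",
    "responding_fraction",
    "label_hotspots",
    "classify_insitu_cell",
    "sd_projection",
    "run_insitu_pipeline",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Square tiling of the analysed FOV region."""

    cell_px: int
    n_rows: int
    n_cols: int
    cell_area_um2: float
    margin_px: tuple[int, int] = (0, 0)  # cropped (rows, cols) at the far edge

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class EpochSet:
    """Stimulus-locked analysis windows.

    The response window for epoch ``i`` is frames
    ``onset+1 .. onset+post_frames`` (inclusive); ``pre_frames`` before the
    onset are stored for QC.
    """

    onset_frames: tuple
    pre_frames: int = 8
    post_frames: int = 8
    drug_label: str = "CNO"

    def __post_init__(self):
        onsets = tuple(int(f) for f in self.onset_frames)
        object.__setattr__(self, "onset_frames", onsets)
        if len(onsets) < 1:
            raise ParameterError("an epoch set needs at least one onset")
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ParameterError("onset frames must be strictly increasing")
        if self.pre_frames < 0 or self.post_frames < 1:
            raise ParameterError("invalid epoch window lengths")

    @property
    def n_epochs(self) -> int:
        return len(self.onset_frames)


@dataclass
class ResponseCountMap:
    """Per-grid-cell count of suprathreshold epochs (0..n_epochs)."""

    counts: np.ndarray  # (n_rows, n_cols) int
    n_epochs: int
    channel: str  # green_drug | green_lglut | red_alexa
    baseline_max: np.ndarray | None = None  # per-cell pre-window max (QC)
    clipped_epochs: tuple = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_epochs:
            raise DataError("counts outside 0..n_epochs")


@dataclass
class FunctionalMap:
    """Binary per-grid-cell map with its derivation."""

    binary: np.ndarray  # (n_rows, n_cols) bool
    provenance: str

    def __post_init__(self):
        self.binary = np.asarray(self.binary, dtype=bool)


@dataclass(frozen=True)
class Hotspot:
    id: int
    member_cells: tuple  # ((row, col), ...)
    size_cells: int
    area_um2: float


@dataclass
class InSituCellResult:
    responding_fraction: float
    n_hotspots: int
    hotspot_areas_um2: list
    responder: bool
    qc_flags: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def detect_puff_onsets(
    red_z_stack: np.ndarray,
    expected_puffs: int,
    onset_threshold_z: float = 1.0,
    refractory_s: float = 10.0,
    frame_period_ms: float = 30.0,
) -> list[int]:
    """First frames at which the FOV-mean red z-trace crosses the threshold.

    After each onset a refractory period (default half the 20 s puff
    interval) suppresses re-triggering on the same tracer transient.  Raises
    :class:`OnsetDetectionError` unless exactly ``expected_puffs`` onsets are
    found.
    """
    red_z_stack = np.asarray(red_z_stack)
    if red_z_stack.ndim != 3:
        raise ParameterError("expected a 3-D (t, y, x) red z-stack")
    if expected_puffs < 1:
        raise ParameterError("expected_puffs must be >= 1")
    if refractory_s < 0 or frame_period_ms <= 0:
        raise ParameterError("invalid timing parameters")
    trace = red_z_stack.mean(axis=(1, 2))
    refractory_frames = int(round(refractory_s * 1000.0 / frame_period_ms))
    above = trace >= onset_threshold_z
    onsets: list[int] = []
    i = 0
    n = len(trace)
    while i < n:
        if above[i]:
            onsets.append(i)
            i += max(refractory_frames, 1)
        else:
            i += 1
    if len(onsets) != expected_puffs:
        raise OnsetDetectionError(found=len(onsets), expected=expected_puffs)
    return onsets


def build_grid(
    fov_shape_px: tuple[int, int], pixel_size_um: float, cell_px: int = 4
) -> GridSpec:
    """Tile the largest ``cell_px``-aligned region of the FOV; residual edge
    pixels are cropped and reported as the margin."""
    h, w = fov_shape_px
    if cell_px < 1:
        raise ParameterError("cell_px must be >= 1")
    if cell_px > min(h, w):
        raise ParameterError(f"grid cell ({cell_px} px) exceeds the FOV ({h}x{w})")
    if pixel_size_um <= 0:
        raise ParameterError("pixel size must be positive")
    n_rows, n_cols = h // cell_px, w // cell_px
    area = (cell_px * pixel_size_um) ** 2
    return GridSpec(
        cell_px=cell_px,
        n_rows=n_rows,
        n_cols=n_cols,
        cell_area_um2=area,
        margin_px=(h - n_rows * cell_px, w - n_cols * cell_px),
    )


def _grid_traces(z_stack: np.ndarray, grid: GridSpec, aggregation: str) -> np.ndarray:
    """(t, n_rows, n_cols) per-cell trace: mean (default) or max over member pixels."""
    t = z_stack.shape[0]
    c = grid.cell_px
    cropped = z_stack[:, : grid.n_rows * c, : grid.n_cols * c]
    blocks = cropped.reshape(t, grid.n_rows, c, grid.n_cols, c)
    if aggregation == "mean":
        return blocks.mean(axis=(2, 4))
    if aggregation == "max":
        return blocks.max(axis=(2, 4))
    raise ParameterError(f"unknown grid aggregation {aggregation!r}")


def grid_epoch_responses(
    z_stack: np.ndarray,
    grid: GridSpec,
    epochs: EpochSet,
    response_threshold_z: float = 2.0,
    channel: str = "green_drug",
    aggregation: str = "mean",
    time_locked: bool = False,
) -> ResponseCountMap:
    """Count, per grid cell, the epochs whose post-onset window maximum of the
    cell's aggregated z-trace reaches the threshold (inclusive).

    The response rule uses absolute z units over the whole acquisition; the
    pre-window maximum is stored for QC.  With ``time_locked=True`` an epoch
    additionally requires the pre-window maximum to stay below threshold.
    Windows extending past the acquisition are clipped and flagged.
    """
    z_stack = np.asarray(z_stack)
    if z_stack.ndim != 3:
        raise ParameterError("expected a 3-D (t, y, x) z-stack")
    h, w = z_stack.shape[1:]
    if grid.n_rows * grid.cell_px > h or grid.n_cols * grid.cell_px > w:
        raise ParameterError("grid does not fit the stack FOV")
    n = z_stack.shape[0]
    if any(o < 0 or o >= n for o in epochs.onset_frames):
        raise ParameterError("epoch onset outside the acquisition")
    traces = _grid_traces(z_stack, grid, aggregation)
    counts = np.zeros((grid.n_rows, grid.n_cols), dtype=int)
    baseline_max = np.full((grid.n_rows, grid.n_cols), -np.inf)
    clipped = []
    for eid, onset in enumerate(epochs.onset_frames):
        start = onset + 1
        stop = onset + epochs.post_frames + 1
        if stop > n:
            stop = n
            clipped.append(eid)
        if start >= stop:
            continue
        post_max = traces[start:stop].max(axis=0)
        hit = post_max >= response_threshold_z
        pre_start = max(0, onset - epochs.pre_frames)
        if onset > pre_start:
            pre_max = traces[pre_start:onset].max(axis=0)
            np.maximum(baseline_max, pre_max, out=baseline_max)
            if time_locked:
                hit &= pre_max < response_threshold_z
        counts += hit
    return ResponseCountMap(
        counts=counts,
        n_epochs=epochs.n_epochs,
        channel=channel,
        baseline_max=baseline_max,
        clipped_epochs=tuple(clipped),
    )


def reliability_maps(
    green_counts: ResponseCountMap,
    alexa_counts: ResponseCountMap,
    min_green: int = 4,
    alexa_rule: str = "all_puffs",
    motion_mask: np.ndarray | None = None,
) -> FunctionalMap:
    """Cells with >= ``min_green`` green responses whose tracer delivery
    satisfies ``alexa_rule`` ("all_puffs" or "min_green"), minus any
    motion-excluded cells."""
    if green_counts.counts.shape != alexa_counts.counts.shape:
        raise DataError("green and tracer count maps are on different grids")
    if alexa_rule == "all_puffs":
        alexa_ok = alexa_counts.counts >= alexa_counts.n_epochs
    elif alexa_rule == "min_green":
        alexa_ok = alexa_counts.counts >= min_green
    else:
        raise ParameterError(f"unknown alexa_rule {alexa_rule!r}")
    binary = (green_counts.counts >= min_green) & alexa_ok
    if motion_mask is not None:
        motion_mask = np.asarray(motion_mask, dtype=bool)
        if motion_mask.shape != binary.shape:
            raise DataError("motion mask shape differs from the grid")
        binary &= ~motion_mask
    return FunctionalMap(
        binary=binary,
        provenance=(
            f"green>={min_green}/{green_counts.n_epochs} & tracer:{alexa_rule}"
            + (" & motion-excluded" if motion_mask is not None else "")
        ),
    )


def intersect_maps(drug_map: FunctionalMap, lglut_map: FunctionalMap) -> FunctionalMap:
    if drug_map.binary.shape != lglut_map.binary.shape:
        raise DataError("maps are on different grids")
    return FunctionalMap(
        binary=drug_map.binary & lglut_map.binary,
        provenance=f"({drug_map.provenance}) AND ({lglut_map.provenance})",
    )


def responding_fraction(
    intersection_map: FunctionalMap, lglut_map: FunctionalMap
) -> float:
    """|drug AND control| / |control|; refuses when the control map is empty."""
    if intersection_map.binary.shape != lglut_map.binary.shape:
        raise DataError("maps are on different grids")
    denom = int(lglut_map.binary.sum())
    if denom == 0:
        raise MissingControlError(
            "positive-control map is empty; responding fraction undefined"
        )
    return float(intersection_map.binary.sum()) / denom


def label_hotspots(
    functional_map: FunctionalMap,
    grid: GridSpec,
    min_size: int = 4,
    connectivity: int = 8,
) -> list[Hotspot]:
    """Connected components of active grid cells with at least ``min_size``
    members (8-neighbour connectivity by default)."""
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    if min_size < 1:
        raise ParameterError("min_size must be >= 1")
    labels = measure.label(
        functional_map.binary, connectivity=1 if connectivity == 4 else 2
    )
    hotspots = []
    for lab in range(1, labels.max() + 1):
        cells = np.argwhere(labels == lab)
        if len(cells) < min_size:
            continue
        hotspots.append(
            Hotspot(
                id=len(hotspots),
                member_cells=tuple(map(tuple, cells.tolist())),
                size_cells=len(cells),
                area_um2=len(cells) * grid.cell_area_um2,
            )
        )
    return hotspots


def classify_insitu_cell(
    fraction: float,
    hotspots: list[Hotspot],
    responder_threshold: float = 0.05,
    qc_flags: dict | None = None,
) -> InSituCellResult:
    """Responder iff the responding fraction reaches the threshold (inclusive)."""
    if not (0.0 <= fraction <= 1.0):
        raise ParameterError("fraction must be within [0, 1]")
    if responder_threshold <= 0:
        raise ParameterError("responder_threshold must be positive")
    return InSituCellResult(
        responding_fraction=fraction,
        n_hotspots=len(hotspots),
        hotspot_areas_um2=[h.area_um2 for h in hotspots],
        responder=fraction >= responder_threshold,
        qc_flags=dict(qc_flags or {}),
    )


def sd_projection(z_stack: np.ndarray, epochs: EpochSet) -> dict:
    """Per-pixel SD over the concatenated pre/post epoch windows only.

    Returns the SD image, the per-epoch mean projections and the number of
    frames that entered the computation.
    """
    z_stack = np.asarray(z_stack)
    if z_stack.ndim != 3:
        raise ParameterError("expected a 3-D (t, y, x) z-stack")
    n = z_stack.shape[0]
    mask = np.zeros(n, dtype=bool)
    epoch_means = []
    for onset in epochs.onset_frames:
        pre_start = max(0, onset - epochs.pre_frames)
        stop = min(n, onset + epochs.post_frames + 1)
        mask[pre_start:onset] = True
        mask[onset + 1:stop] = True
        if onset + 1 < stop:
            epoch_means.append(z_stack[onset + 1:stop].mean(axis=0))
    if not mask.any():
        raise ParameterError("epoch windows select no frames")
    sd = z_stack[mask].std(axis=0, ddof=0)
    return {"sd": sd, "epoch_means": epoch_means, "n_frames_used": int(mask.sum())}


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def _assert_subset_chain(intersection: FunctionalMap, drug: FunctionalMap) -> None:
    if np.any(intersection.binary & ~drug.binary):
        raise DataError("invariant violated: intersection not a subset of the drug map")


def run_insitu_pipeline(
    drug_green_z: np.ndarray,
    drug_red_z: np.ndarray,
    lglut_green_z: np.ndarray,
    lglut_red_z: np.ndarray,
    pixel_size_um: float,
    frame_period_ms: float = 30.0,
    n_puffs: int = 6,
    cell_px: int = 4,
    response_threshold_z: float = 2.0,
    onset_threshold_z: float = 1.0,
    min_green: int = 4,
    min_hotspot_size: int = 4,
    responder_threshold: float = 0.05,
    lglut_window_s: float = 2.0,
    drug_window_frames: int = 8,
    refractory_s: float = 10.0,
    motion_mask: np.ndarray | None = None,
) -> dict:
    """Full slice analysis on preprocessed (z-scored) drug and control stacks.

    Returns the cell result plus all intermediate maps and hotspot tables.
    """
    grid = build_grid(drug_green_z.shape[1:], pixel_size_um, cell_px)

    def _epochs(red_z, post_frames, label):
        onsets = detect_puff_onsets(
            red_z, n_puffs, onset_threshold_z, refractory_s, frame_period_ms
        )
        return EpochSet(
            onset_frames=tuple(onsets),
            pre_frames=post_frames,
            post_frames=post_frames,
            drug_label=label,
        )

    lglut_window_frames = int(round(lglut_window_s * 1000.0 / frame_period_ms))
    drug_epochs = _epochs(drug_red_z, drug_window_frames, "drug")
    lglut_epochs = _epochs(lglut_red_z, lglut_window_frames, "lglut")

    maps = {}
    for tag, green_z, red_z, eps in (
        ("drug", drug_green_z, drug_red_z, drug_epochs),
        ("lglut", lglut_green_z, lglut_red_z, lglut_epochs),
    ):
        green_counts = grid_epoch_responses(
            green_z, grid, eps, response_threshold_z, channel=f"green_{tag}"
        )
        alexa_counts = grid_epoch_responses(
            red_z, grid, eps, response_threshold_z, channel="red_alexa"
        )
        maps[tag] = reliability_maps(
            green_counts, alexa_counts, min_green=min_green, motion_mask=motion_mask
        )
        maps[f"{tag}_counts"] = green_counts
        maps[f"{tag}_alexa_counts"] = alexa_counts

    intersection = intersect_maps(maps["drug"], maps["lglut"])
    _assert_subset_chain(intersection, maps["drug"])
    _assert_subset_chain(intersection, maps["lglut"])
    fraction = responding_fraction(intersection, maps["lglut"])
    hotspots = label_hotspots(intersection, grid, min_size=min_hotspot_size)
    qc = {
        "clipped_drug_epochs": maps["drug_counts"].clipped_epochs,
        "clipped_lglut_epochs": maps["lglut_counts"].clipped_epochs,
    }
    result = classify_insitu_cell(fraction, hotspots, responder_threshold, qc)
    return {
        "result": result,
        "grid": grid,
        "drug_epochs": drug_epochs,
        "lglut_epochs": lglut_epochs,
        "drug_map": maps["drug"],
        "lglut_map": maps["lglut"],
        "intersection_map": intersection,
        "drug_counts": maps["drug_counts"],
        "lglut_counts": maps["lglut_counts"],
        "hotspots": hotspots,
    }
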