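"""Run configuration: every analysis parameter with its published default.

The config round-trips losslessly through YAML; unknown keys raise a
:class:`~gluimg.errors.ParameterError` naming the offending key so typos
cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["RunConfig", "PARAMETER_DEFAULTS"]


# Literal defaults in one place so tests can assert each value directly.
PARAMETER_DEFAULTS = {
    # acquisition
    "frame_period_ms": 30.0,
    "insitu_pixel_size_um": 0.293,
    "invivo_pixel_size_um": 1.18,
    "insitu_duration_s": 120.0,
    "invivo_duration_s": 60.0,
    # stimulation
    "n_puffs": 6,
    "puff_interval_s": 20.0,
    # event kinetics
    "rise_ms": 100.0,
    "decay_ms": 450.0,
    # preprocessing
    "nlm_patch_size": 2,
    "nlm_patch_distance": 4,
    "nlm_h": 0.8,
    "gaussian_sigma_x": 0.5,
    "gaussian_sigma_y": 0.5,
    "gaussian_sigma_t": 0.5,
    # in situ grid analysis
    "grid_cell_px": 4,
    "onset_threshold_z": 1.0,
    "response_threshold_z": 2.0,
    "drug_window_frames": 8,
    "lglut_window_s": 2.0,
    "min_green_responses": 4,
    "min_hotspot_size": 4,
    "hotspot_connectivity": 8,
    "responder_threshold": 0.05,
    # in vivo ROI analysis
    "motion_smooth_sigma": 3.0,
    "motion_contrast_threshold": 1.2,
    "max_shift_px": 5.0,
    "n_max_rois": 50,
    "min_roi_pixels": 5,
    "min_event_ms": 150.0,
    "max_event_ms": 2000.0,
    "blocker_min_event_ms": 500.0,
    "blocker_max_event_ms": 10000.0,
    "amp_threshold_z": 2.0,
    "min_fwhm_ms": 250.0,
    "min_frequency_increase": 0.25,
    "area_threshold": 0.03,
    "alpha": 0.05,
    "effect_window_s": 10.0,
    "hotspot_blur_sigma": 1.0,
}


def _block(prefix: str, rename: dict | None = None) -> dict:
    rename = rename or {}
    return {
        rename.get(k, k[len(prefix):]): v
        for k, v in PARAMETER_DEFAULTS.items()
        if k.startswith(prefix)
    }


@dataclass
class RunConfig:
    """Paths, pipeline selection and all parameter blocks for one run."""

    pipeline: str = "insitu"  # insitu | invivo | simulate
    green_path: str | None = None
    red_path: str | None = None
    lglut_green_path: str | None = None
    lglut_red_path: str | None = None
    output_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    frame_period_ms: float = PARAMETER_DEFAULTS["frame_period_ms"]
    pixel_size_um: float | None = None
    stim_onset_s: float | None = None
    preprocess: dict = field(
        default_factory=lambda: {
            k: PARAMETER_DEFAULTS[k]
            for k in (
                "nlm_patch_size", "nlm_patch_distance", "nlm_h",
                "gaussian_sigma_x", "gaussian_sigma_y", "gaussian_sigma_t",
            )
        }
    )
    insitu: dict = field(
        default_factory=lambda: {
            k: PARAMETER_DEFAULTS[k]
            for k in (
                "n_puffs", "grid_cell_px", "onset_threshold_z",
                "response_threshold_z", "drug_window_frames", "lglut_window_s",
                "min_green_responses", "min_hotspot_size",
                "hotspot_connectivity", "responder_threshold",
            )
        }
    )
    invivo: dict = field(
        default_factory=lambda: {
            k: PARAMETER_DEFAULTS[k]
            for k in (
                "motion_smooth_sigma", "motion_contrast_threshold",
                "max_shift_px", "n_max_rois", "min_roi_pixels",
                "min_event_ms", "max_event_ms", "amp_threshold_z",
                "min_fwhm_ms", "min_frequency_increase", "area_threshold",
                "alpha", "effect_window_s", "hotspot_blur_sigma",
            )
        }
    )

    def __post_init__(self):
        if self.pipeline not in ("insitu", "invivo", "simulate"):
            raise ParameterError(f"unknown pipeline {self.pipeline!r}")

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        base = cls()
        merged = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                merged[f.name] = getattr(base, f.name)
                continue
            value = data[f.name]
            if f.name in ("preprocess", "insitu", "invivo"):
                defaults = getattr(base, f.name)
                bad = set(value) - set(defaults)
                if bad:
                    raise ParameterError(
                        f"unknown {f.name} config key(s): {', '.join(sorted(bad))}"
                    )
                merged[f.name] = {**defaults, **value}
            else:
                merged[f.name] = value
        return cls(**merged)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text_or_path) -> "RunConfig":
        if isinstance(text_or_path, Path):
            text = text_or_path.read_text()
        else:
            text = str(text_or_path)
            if "\n" not in text and Path(text).exists():
                text = Path(text).read_text()
        data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ParameterError("config must be a mapping of keys to values")
        return cls.from_dict(data)
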