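"""TIFF/CSV/JSON input and output with checksummed run records."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError, ParameterError
from .preprocess import TwoChannelMovie

__all__ = ["RunRecord", "read_movie", "write_results", "sha256_file"]


def sha256_file(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    config_snapshot: dict
    software_version: str
    input_checksums: dict = field(default_factory=dict)
    started_at: str = ""
    finished_at: str = ""
    stage_status: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    output_files: dict = field(default_factory=dict)  # name -> checksum

    @staticmethod
    def now() -> str:
        return datetime.now(timezone.utc).isoformat()

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def _read_stack(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise DataError(f"movie file not found: {path}")
    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various types on corrupt input
        raise DataError(f"unreadable TIFF {path}: {exc}") from exc
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise DataError(f"{path}: expected a (t, y, x) stack, got shape {stack.shape}")
    return stack.astype(np.float32)


def read_movie(
    path_green,
    path_red,
    frame_period_ms: float,
    pixel_size_um: float,
    metadata: dict | None = None,
) -> TwoChannelMovie:
    """Load a two-channel movie from paired multi-page TIFF stacks."""
    if frame_period_ms is None or frame_period_ms <= 0:
        raise ParameterError("frame_period_ms is required and must be positive")
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ParameterError("pixel_size_um is required and must be positive")
    green = _read_stack(path_green)
    red = _read_stack(path_red)
    if green.shape != red.shape:
        raise DataError(
            f"channel mismatch: green {green.shape} vs red {red.shape} "
            f"({path_green} vs {path_red})"
        )
    return TwoChannelMovie(
        green=green,
        red=red,
        frame_period_ms=frame_period_ms,
        pixel_size_um=pixel_size_um,
        metadata=dict(metadata or {}),
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set)):
        return list(obj)
    return str(obj)


def write_results(results: dict, out_dir, record: RunRecord | None = None) -> dict:
    """Write analysis outputs and return a checksummed manifest.

    ``results`` maps output names to objects; the extension chooses the
    writer: arrays -> ``.tif`` (16-bit for boolean/integer label data,
    32-bit float otherwise), DataFrames -> ``.csv``, dicts/lists -> ``.json``.
    Identical inputs reproduce identical checksums.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write-probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory not writable: {out}") from exc

    manifest_files: dict[str, str] = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False)
        elif isinstance(obj, np.ndarray):
            path = out / f"{name}.tif"
            if obj.dtype == bool or np.issubdtype(obj.dtype, np.integer):
                data = obj.astype(np.uint16)
            else:
                data = obj.astype(np.float32)
            tifffile.imwrite(path, data, photometric="minisblack")
        elif isinstance(obj, (dict, list)):
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
        else:
            raise ParameterError(
                f"unsupported result type for {name!r}: {type(obj).__name__}"
            )
        manifest_files[path.name] = sha256_file(path)

    manifest = {"files": manifest_files, "n_files": len(manifest_files)}
    if record is not None:
        record.output_files = dict(manifest_files)
        record.finished_at = RunRecord.now()
        record_path = out / "run_record.json"
        record_path.write_text(record.to_json())
        manifest["run_record"] = record_path.name
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
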