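"""File formats, configuration and run reporting.

Image stacks travel as multi-page grayscale TIFF (8- or 16-bit; 16-bit input
is rescaled to 8-bit with the scaling logged). Tabular outputs are plain CSV
with the schemas defined by the stage that produces them. Run configuration
is a YAML document that round-trips unchanged; every defaulted parameter is
echoed into the run log so no default is silent.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml

from .types import SceneSpec, SegmentationParams, TrackingParams

__all__ = [
    "read_stack",
    "write_stack",
    "load_config",
    "dump_config",
    "config_with_defaults",
    "write_report",
    "REPORT_SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


class _ErrorTrap(logging.Handler):
    """Collects ERROR-level messages emitted by a third-party logger."""

    def __init__(self) -> None:
        super().__init__(level=logging.ERROR)
        self.records: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.records.append(record.getMessage())

#: Default run configuration; every key is overridable from YAML and echoed
#: into the run log. Physical constants live here, never hard-coded in the
#: operations.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "cellcharge_out",
    "log_level": "INFO",
    "input_tiff": None,
    "simulate": {
        "n_cells": 50,
        "charge": {
            "family": "lognormal-magnitude-with-sign",
            "params": {
                "median_C": 2.0e-17,
                "sigma_log": 1.0,
                "sign": -1.0,
                "support_C": [1.0e-18, 1.8e-16],
            },
        },
        "E_V_per_m": 380.0,
        "on_intervals": [[0.0, 10.0]],
        "D_um2_s": 0.16,
        "viscosity_Pa_s": 1.0e-3,
        "radius_m": 5.0e-7,
        "pH": 5.8,
        "scene": {
            "width_px": 512,
            "height_px": 512,
            "n_frames": 50,
            "frame_interval_s": 0.2,
            "pixel_scale_um": 0.093,
            "cell_radius_px": 6.0,
            "background_level": 200,
            "cell_level": 60,
            "psf_sigma_px": 1.0,
            "noise_sigma": 3.0,
        },
        "placement": {"min_separation_px": 10.0, "x_banded": False},
    },
    "segmentation": {f.name: f.default for f in dataclasses.fields(SegmentationParams)},
    "tracking": {
        f.name: f.default for f in dataclasses.fields(TrackingParams) if f.name != "seed"
    },
    "kinematics": {"max_lag_frames": None, "fit_fraction": 1.0},
    "electrokinetics": {
        "E_V_per_m": 380.0,
        "current_A": None,
        "conductivity_S_per_m": None,
        "electrode_cross_section_m2": None,
        "viscosity_Pa_s": 1.0e-3,
        "radius_m": 5.0e-7,
        "axis_unit_vector": [0.0, 1.0],
    },
}


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a uint8 (n_frames, h, w) array.

    16-bit input is min-max rescaled to 8-bit (scaling logged); RGB or
    multi-channel input raises an unsupported-format error. A truncated file
    raises an error naming the last frame successfully read.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    # tifffile drops pages with out-of-file IFD offsets silently (it only
    # logs); trap its error records so truncation surfaces as an exception
    sentinel = _ErrorTrap()
    tiff_logger = logging.getLogger("tifffile")
    tiff_logger.addHandler(sentinel)
    try:
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                try:
                    frames.append(page.asarray())
                except Exception as exc:  # damaged page data
                    raise IOError(
                        f"truncated TIFF {path}: failed at frame {i} "
                        f"after reading {len(frames)} frame(s)"
                    ) from exc
    except tifffile.TiffFileError as exc:
        raise IOError(f"unreadable TIFF {path}: {exc}") from exc
    finally:
        tiff_logger.removeHandler(sentinel)
    if sentinel.records:
        raise IOError(
            f"truncated TIFF {path}: {sentinel.records[0]}; "
            f"last intact frame index {len(frames) - 1}"
        )
    if not frames:
        raise IOError(f"no frames in {path}")
    stack = np.stack(frames)
    if stack.ndim != 3:
        raise ValueError(
            f"unsupported format: expected grayscale pages, got shape {stack.shape} "
            "(multi-channel/RGB input is not supported)"
        )
    if stack.dtype == np.uint8:
        return stack
    if stack.dtype == np.uint16:
        lo, hi = int(stack.min()), int(stack.max())
        scale = 255.0 / (hi - lo) if hi > lo else 1.0
        logger.info("rescaling 16-bit stack to 8-bit: min=%d max=%d scale=%.6g", lo, hi, scale)
        return ((stack.astype(np.float64) - lo) * scale).clip(0, 255).astype(np.uint8)
    raise ValueError(f"unsupported TIFF dtype {stack.dtype}; expected uint8 or uint16")


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a uint8 stack as multi-page grayscale TIFF."""
    if stack.dtype != np.uint8 or stack.ndim != 3:
        raise ValueError("stack must be uint8 with shape (n_frames, h, w)")
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


def _deep_update(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise KeyError(f"invalid config key: {k!r}")
        if k == "charge":  # family-specific params: replaced wholesale
            out[k] = v
        elif isinstance(v, dict) and isinstance(base[k], dict):
            out[k] = _deep_update(base[k], v)
        else:
            out[k] = v
    return out


def config_with_defaults(overrides: dict | None = None) -> dict:
    """Merge user overrides onto the full default config (unknown keys raise)."""
    return _deep_update(DEFAULT_CONFIG, overrides or {})


def load_config(path: str | Path) -> dict:
    """Load a YAML config file and merge it with defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return config_with_defaults(user)


def dump_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def scene_from_config(cfg: dict, seed: int) -> SceneSpec:
    sc = cfg["simulate"]["scene"]
    return SceneSpec(
        width_px=sc["width_px"],
        height_px=sc["height_px"],
        pixel_scale_um=sc["pixel_scale_um"],
        frame_interval_s=sc["frame_interval_s"],
        n_frames=sc["n_frames"],
        cell_radius_px=sc["cell_radius_px"],
        background_level=sc["background_level"],
        cell_level=sc["cell_level"],
        psf_sigma_px=sc["psf_sigma_px"],
        noise_sigma=sc["noise_sigma"],
        seed=seed,
    )


def segmentation_params_from_config(cfg: dict) -> SegmentationParams:
    return SegmentationParams(**cfg["segmentation"])


def tracking_params_from_config(cfg: dict, seed: int) -> TrackingParams:
    return TrackingParams(seed=seed, **cfg["tracking"])


def write_report(report: dict, path: str | Path) -> None:
    """Serialise a run report as JSON plus a human-readable text twin."""
    path = Path(path)
    report = {"schema_version": REPORT_SCHEMA_VERSION, **report}
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    txt = path.with_suffix(".txt")
    with open(txt, "w") as fh:
        fh.write(_render_report(report))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _render_report(report: dict, indent: int = 0) -> str:
    lines = []
    pad = "  " * indent
    for k, v in report.items():
        if isinstance(v, dict):
            lines.append(f"{pad}{k}:")
            lines.append(_render_report(v, indent + 1))
        else:
            lines.append(f"{pad}{k}: {v}")
    return "\n".join(lines)
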