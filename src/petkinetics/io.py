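"""File formats: TIFF movies with JSON sidecars, CSV tables, JSON fits, YAML config.

Movies travel as plain multi-page TIFF (frame-major) with acquisition
metadata in a ``<name>.json`` sidecar next to the file; event tables and
traces are CSV with headers; fit results are JSON. Nothing here parses
vendor metadata — a TIFF plus its sidecar is the whole contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import BindingEvent
from .errors import StructuralError
from .kymograph import Kymograph, MovieStack
from .photobleach import IntensityTrace
from .simulate import GroundTruthEvent, SimulationConfig
from .survival import ExpFit, SurvivalCurve

__all__ = [
    "save_movie",
    "load_movie",
    "save_kymograph",
    "load_kymograph",
    "write_events_csv",
    "read_events_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_survival_csv",
    "fit_to_dict",
    "save_fit_json",
    "load_simulation_config",
    "save_simulation_config",
    "config_hash",
]

_MOVIE_META = ("frame_interval", "pixel_size", "fov_area", "concentration", "laser_power")


def _sidecar(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def save_movie(movie: MovieStack, path) -> Path:
    """Write a movie as multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.intensity.astype(np.float32))
    meta = {k: getattr(movie, k) for k in _MOVIE_META}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_movie(path, **overrides) -> MovieStack:
    """Read a TIFF movie; metadata from its sidecar, overridable by keyword."""
    path = Path(path)
    stack = np.asarray(tifffile.imread(path), dtype=float)
    if stack.ndim == 2:
        stack = stack[None, ...]
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    meta.update(overrides)
    if "frame_interval" not in meta or meta["frame_interval"] is None:
        raise StructuralError(f"no frame_interval for movie {path}")
    return MovieStack(intensity=stack, **{k: meta.get(k) for k in _MOVIE_META})


def save_kymograph(kymo: Kymograph, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, kymo.image.astype(np.float32))
    meta = {
        "frame_interval": kymo.frame_interval,
        "output_spacing": kymo.output_spacing,
        "projection_mode": kymo.projection_mode,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_kymograph(path, **overrides) -> Kymograph:
    path = Path(path)
    image = np.asarray(tifffile.imread(path), dtype=float)
    meta = {"frame_interval": 0.2, "output_spacing": None, "projection_mode": "max"}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    meta.update(overrides)
    return Kymograph(image=image, **meta)


_EVENT_COLUMNS = [
    "movie_id",
    "x_px",
    "start_frame",
    "duration_frames",
    "duration_s",
    "left_censored",
    "right_censored",
]


def write_events_csv(events: list[BindingEvent], path, movie_id: str = "") -> Path:
    """Detected events to CSV (one row per streak)."""
    rows = [
        {
            "movie_id": movie_id,
            "x_px": e.x,
            "start_frame": e.start_frame,
            "duration_frames": e.duration_frames,
            "duration_s": e.duration_s,
            "left_censored": e.left_censored,
            "right_censored": e.right_censored,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_events_csv(path) -> list[BindingEvent]:
    df = pd.read_csv(path)
    return [
        BindingEvent(
            x=int(r.x_px),
            start_frame=int(r.start_frame),
            duration_frames=int(r.duration_frames),
            duration_s=float(r.duration_s),
            left_censored=bool(r.left_censored),
            right_censored=bool(r.right_censored),
        )
        for r in df.itertuples()
    ]


def write_truth_csv(events: list[GroundTruthEvent], path) -> Path:
    """Ground-truth event list to CSV (x_um, y_um, t_land_s, dwell_s, population)."""
    rows = [
        {
            "x_um": e.x,
            "y_um": e.y,
            "t_land_s": e.landing_time,
            "dwell_s": e.true_dwell,
            "population": e.population,
            "truncated_by_bleach": e.truncated_by_bleach,
        }
        for e in events
    ]
    cols = ["x_um", "y_um", "t_land_s", "dwell_s", "population", "truncated_by_bleach"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return Path(path)


def read_truth_csv(path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path)
    return [
        GroundTruthEvent(
            x=float(r.x_um),
            y=float(r.y_um),
            landing_time=float(r.t_land_s),
            true_dwell=float(r.dwell_s),
            population=str(r.population),
            truncated_by_bleach=bool(r.truncated_by_bleach),
        )
        for r in df.itertuples()
    ]


def write_trace_csv(trace: IntensityTrace, path) -> Path:
    pd.DataFrame({"t_s": trace.times, "mean_intensity": trace.mean_intensity}).to_csv(
        path, index=False
    )
    return Path(path)


def read_trace_csv(path, laser_power: float | None = None) -> IntensityTrace:
    df = pd.read_csv(path)
    return IntensityTrace(
        times=df["t_s"].to_numpy(),
        mean_intensity=df["mean_intensity"].to_numpy(),
        laser_power=laser_power,
    )


def write_survival_csv(curve: SurvivalCurve, path) -> Path:
    pd.DataFrame({"t_s": curve.times, "survival": curve.survival}).to_csv(path, index=False)
    return Path(path)


def fit_to_dict(fit: ExpFit) -> dict:
    return dataclasses.asdict(fit)


def save_fit_json(fit: ExpFit, path) -> Path:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=1))
    return Path(path)


def save_simulation_config(config: SimulationConfig, path) -> Path:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))
    return Path(path)


def load_simulation_config(path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    return SimulationConfig(**data)


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable config mapping."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
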