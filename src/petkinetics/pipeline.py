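"""End-to-end orchestration: movies → kymographs → events → fits → summary.

A run is described by a :class:`RunConfig`: a list of input movies (TIFF)
or pre-extracted event tables (CSV), each with complete acquisition
metadata and a condition label, plus the analysis parameters. Per movie,
the pipeline builds a kymograph, detects streaks and writes an event
table; per condition, it pools uncensored dwells into a survival fit,
aggregates per-movie landing rates, and emits a kinetic summary row. The
whole run is deterministic given the seed, and every output directory
carries a ``run_meta.json`` sidecar with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .detect import (
    BindingEvent,
    aggregate_landing_rates,
    censor_filter,
    detect_streaks,
    dwell_times,
    landing_count,
    landing_rate,
)
from .errors import ParameterError
from .kinetics import KineticSummary, summarize_condition
from .kymograph import kymograph_from_movie
from .simulate import (
    GroundTruthEvent,
    SimulationConfig,
    render_movie,
    simulate_landing_events,
)
from .survival import empirical_survival, fit_biexponential, fit_monoexponential

logger = logging.getLogger("petkinetics")

__all__ = [
    "MovieInput",
    "RunConfig",
    "PipelineResult",
    "events_from_truth",
    "run_pipeline",
    "simulate_cohort",
    "load_run_config",
]


@dataclass
class MovieInput:
    """One input movie (TIFF) or pre-extracted event table (CSV) plus metadata."""

    condition: str
    movie_path: str | None = None
    events_path: str | None = None
    frame_interval: float = 0.2
    pixel_size: float | None = None
    fov_area: float | None = None
    concentration: float | None = None
    laser_power: float | None = None
    inhibitor: bool = False
    movie_id: str = ""

    def __post_init__(self) -> None:
        if (self.movie_path is None) == (self.events_path is None):
            raise ParameterError("provide exactly one of movie_path or events_path")
        if self.fov_area is None or self.concentration is None:
            raise ParameterError(f"movie {self.movie_id or self.condition}: incomplete metadata")
        if not self.movie_id:
            src = self.movie_path or self.events_path
            self.movie_id = Path(src).stem


@dataclass
class RunConfig:
    """Inputs plus analysis parameters for one reproducible pipeline run."""

    movies: list[MovieInput]
    outdir: str
    seed: int = 0
    output_spacing: int = 5
    projection_mode: str = "max"
    threshold_method: str = "mean_plus_k_sigma"
    k_sigma: float = 4.0
    threshold_value: float | None = None
    min_duration_frames: int = 1
    gap_tolerance_frames: int = 0
    min_width: int = 1
    censor_policy: str = "exclude_censored"
    fit_model: str = "bi"  # "bi" | "mono"
    movie_duration_s: float | None = None  # overrides n_frames × frame_interval

    def __post_init__(self) -> None:
        if not self.movies:
            raise ParameterError("empty input list")


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    fits: dict
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def events_from_truth(
    truth: list[GroundTruthEvent], config: SimulationConfig
) -> list[BindingEvent]:
    """Convert ground-truth events to the detected-event representation.

    Applies the same frame discretization and boundary-censoring flags the
    imaging path would produce, so the statistical stages can be exercised
    without rendering or detection.
    """
    n_frames = config.n_frames
    out = []
    for ev in truth:
        f0, f1 = ev.frame_span(config.frame_interval, n_frames)
        if f1 <= f0:
            continue
        out.append(
            BindingEvent(
                x=int(round(ev.x * 1000.0 / config.pixel_size)),
                start_frame=f0,
                duration_frames=f1 - f0,
                duration_s=(f1 - f0) * config.frame_interval,
                left_censored=f0 == 0,
                right_censored=f1 == n_frames,
            )
        )
    out.sort(key=lambda e: (e.start_frame, e.x))
    return out


def _movie_events(cfg: RunConfig, movie: MovieInput) -> tuple[list[BindingEvent], float]:
    """Detect (or load) events for one movie; returns (events, movie duration s)."""
    if movie.events_path is not None:
        events = pio.read_events_csv(movie.events_path)
        if cfg.movie_duration_s is not None:
            duration = cfg.movie_duration_s
        else:
            last = max((e.start_frame + e.duration_frames for e in events), default=1)
            duration = last * movie.frame_interval
        return events, duration
    stack = pio.load_movie(
        movie.movie_path,
        frame_interval=movie.frame_interval,
        pixel_size=movie.pixel_size,
        fov_area=movie.fov_area,
        concentration=movie.concentration,
        laser_power=movie.laser_power,
    )
    kymo = kymograph_from_movie(stack, cfg.output_spacing, cfg.projection_mode)
    events = detect_streaks(
        kymo,
        threshold_method=cfg.threshold_method,
        k_sigma=cfg.k_sigma,
        min_duration_frames=cfg.min_duration_frames,
        gap_tolerance_frames=cfg.gap_tolerance_frames,
        min_width=cfg.min_width,
        threshold_value=cfg.threshold_value,
    )
    return events, stack.n_frames * movie.frame_interval


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis; per-movie failures are recorded, not fatal."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(log_handler)
    errors: list[str] = []
    by_condition: dict[tuple[str, bool], dict] = {}

    try:
        for movie in config.movies:
            try:
                events, duration = _movie_events(config, movie)
            except Exception as exc:  # noqa: BLE001 — keep the cohort running
                msg = f"movie {movie.movie_id}: {exc}"
                logger.error(msg)
                errors.append(msg)
                continue
            pio.write_events_csv(
                events, outdir / f"events_{movie.movie_id}.csv", movie_id=movie.movie_id
            )
            rate = landing_rate(
                landing_count(events), movie.fov_area, duration, movie.concentration
            )
            key = (movie.condition, movie.inhibitor)
            bucket = by_condition.setdefault(key, {"dwells": [], "rates": []})
            bucket["dwells"].append(dwell_times(events, config.censor_policy))
            bucket["rates"].append(rate)
            logger.info(
                "movie %s: %d events, %d uncensored, rate %.3g /um2/s/M",
                movie.movie_id, len(events), len(bucket["dwells"][-1]), rate,
            )

        rows, fits = [], {}
        for (condition, inhibitor), bucket in sorted(by_condition.items()):
            dwells = np.concatenate(bucket["dwells"]) if bucket["dwells"] else np.array([])
            frame_interval = config.movies[0].frame_interval
            label = condition + ("+inhibitor" if inhibitor else "")
            try:
                curve = empirical_survival(dwells, min_observable=frame_interval)
                fit = (
                    fit_biexponential(curve)
                    if config.fit_model == "bi"
                    else fit_monoexponential(curve)
                )
            except Exception as exc:  # noqa: BLE001
                msg = f"condition {label}: fit failed ({exc})"
                logger.error(msg)
                errors.append(msg)
                continue
            landing = aggregate_landing_rates(bucket["rates"])
            summary = summarize_condition(condition, fit, landing, inhibitor)
            rows.append(dataclasses.asdict(summary))
            fits[label] = fit
            pio.save_fit_json(fit, outdir / f"fit_{label}.json")
            pio.write_survival_csv(curve, outdir / f"survival_{label}.csv")

        summary_df = pd.DataFrame(rows)
        summary_df.to_csv(outdir / "summary.csv", index=False)
        meta = {
            "seed": config.seed,
            "config_hash": pio.config_hash(config),
            "n_movies": len(config.movies),
            "errors": errors,
        }
        (outdir / "run_meta.json").write_text(json.dumps(meta, indent=1))
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
    return PipelineResult(summary=summary_df, fits=fits, errors=errors)


def simulate_cohort(
    config: SimulationConfig,
    n_movies: int,
    outdir,
    render: bool = True,
    condition: str = "wildtype",
    inhibitor: bool = False,
) -> RunConfig:
    """Simulate a replicate cohort ready for :func:`run_pipeline`.

    Writes one movie per replicate — a rendered TIFF when ``render`` is
    true, otherwise a detected-style event CSV derived from the truth
    table — alongside the ground-truth CSV and the simulation config.
    Per-movie seeds are spawned from ``config.seed`` so the cohort is
    reproducible and replicates are independent.
    """
    if n_movies < 1:
        raise ParameterError("n_movies must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.save_simulation_config(config, outdir / "simulation_config.yaml")
    children = np.random.SeedSequence(config.seed).spawn(n_movies)
    movies = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        truth = simulate_landing_events(config, seed=rng)
        pio.write_truth_csv(truth, outdir / f"truth_{i:03d}.csv")
        common = dict(
            condition=condition,
            inhibitor=inhibitor,
            frame_interval=config.frame_interval,
            pixel_size=config.pixel_size,
            fov_area=config.fov_area,
            concentration=config.concentration,
            movie_id=f"{condition}_{i:03d}",
        )
        if render:
            stack = render_movie(truth, config, seed=rng)
            path = pio.save_movie(stack, outdir / f"movie_{i:03d}.tif")
            movies.append(MovieInput(movie_path=str(path), **common))
        else:
            events = events_from_truth(truth, config)
            path = pio.write_events_csv(
                events, outdir / f"events_in_{i:03d}.csv", movie_id=f"{condition}_{i:03d}"
            )
            movies.append(MovieInput(events_path=str(path), **common))
    return RunConfig(
        movies=movies,
        outdir=str(outdir / "analysis"),
        seed=config.seed,
        movie_duration_s=config.movie_duration,
    )


def load_run_config(path) -> RunConfig:
    """Read a pipeline run description from YAML."""
    data = yaml.safe_load(Path(path).read_text())
    movies = [MovieInput(**m) for m in data.pop("movies", [])]
    analysis = data.pop("analysis", {})
    return RunConfig(movies=movies, **{**data, **analysis})
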