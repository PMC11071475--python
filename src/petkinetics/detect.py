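"""Detect vertical streaks in a kymograph as single-molecule binding events.

An immobile binding event shows up in a position-time kymograph as a
vertical run of bright pixels: its length along the time axis, where one
pixel equals one frame, is the binding duration, and the total number of
streaks over the whole movie gives the landing rate once normalized per
unit area, time and solution enzyme concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import DegenerateThresholdError, ParameterError
from .kymograph import Kymograph

__all__ = [
    "BindingEvent",
    "LandingRateEstimate",
    "detect_streaks",
    "censor_filter",
    "dwell_times",
    "landing_count",
    "landing_rate",
    "aggregate_landing_rates",
]


@dataclass(frozen=True)
class BindingEvent:
    """One detected streak: where it sits, when it starts, how long it lasts.

    Events touching the first or last frame of the movie are flagged
    censored: their true duration extends beyond the acquisition window.
    """

    x: int
    start_frame: int
    duration_frames: int
    duration_s: float
    left_censored: bool = False
    right_censored: bool = False

    def __post_init__(self) -> None:
        if self.duration_frames < 1:
            raise ParameterError("duration_frames must be >= 1")

    @property
    def censored(self) -> bool:
        return self.left_censored or self.right_censored


@dataclass(frozen=True)
class LandingRateEstimate:
    """Normalized landing rate pooled across replicate movies (μm⁻²·s⁻¹·M⁻¹)."""

    per_movie_rates: tuple[float, ...]
    mean: float
    sem: float | None  # undefined (None) for a single movie
    n_movies: int


def _threshold(image: np.ndarray, method: str, k_sigma: float, value) -> float:
    if method == "absolute":
        if value is None:
            raise ParameterError("threshold_method 'absolute' requires threshold_value")
        return float(value)
    if method == "otsu":
        if np.ptp(image) == 0:
            raise DegenerateThresholdError("constant image has no Otsu threshold")
        return float(threshold_otsu(image))
    if method == "mean_plus_k_sigma":
        # Robust spread: MAD scaled to Gaussian sigma, so sparse bright
        # streaks do not inflate the background estimate.
        sigma = float(stats.median_abs_deviation(image, axis=None, scale="normal"))
        if sigma == 0:
            raise DegenerateThresholdError(
                "zero robust spread; use 'otsu' or 'absolute' for noiseless images"
            )
        return float(image.mean()) + k_sigma * sigma
    raise ParameterError(f"unknown threshold_method {method!r}")


def _bridge_time_gaps(mask: np.ndarray, gap: int) -> np.ndarray:
    """Fill dark runs of <= ``gap`` frames between bright runs, per column."""
    if gap <= 0:
        return mask
    out = mask.copy()
    n_rows = mask.shape[0]
    for col in range(mask.shape[1]):
        column = mask[:, col]
        if not column.any():
            continue
        edges = np.flatnonzero(np.diff(column.astype(np.int8)))
        # zero-runs strictly inside the column: (fall+1 .. rise) pairs
        falls = edges[column[edges]]  # index of last True before a gap
        for f in falls:
            nxt = f + 1
            while nxt < n_rows and not column[nxt]:
                nxt += 1
            if nxt < n_rows and (nxt - f - 1) <= gap:
                out[f + 1 : nxt, col] = True
    return out


def detect_streaks(
    kymo: Kymograph,
    threshold_method: str = "mean_plus_k_sigma",
    k_sigma: float = 4.0,
    min_duration_frames: int = 1,
    gap_tolerance_frames: int = 0,
    min_width: int = 1,
    threshold_value: float | None = None,
) -> list[BindingEvent]:
    """Segment above-threshold pixels into binding events.

    Pixels above the threshold are grouped into 8-connected components in
    (x, t), so sub-pixel jitter across adjacent columns does not split an
    event. A component's duration is its extent along the time axis; only
    components spanning at least ``min_duration_frames`` frames and
    ``min_width`` columns are reported. Dark gaps of up to
    ``gap_tolerance_frames`` frames within a column are bridged first
    (default 0: blinking truncates events, matching how observed durations
    are defined). Events touching the first/last frame are flagged censored.
    """
    image = kymo.image
    if image.size == 0:
        raise ParameterError("empty kymograph")
    if min_duration_frames < 1 or min_width < 1:
        raise ParameterError("min_duration_frames and min_width must be >= 1")
    thr = _threshold(image, threshold_method, k_sigma, threshold_value)
    mask = image > thr
    mask = _bridge_time_gaps(mask, gap_tolerance_frames)
    labels = measure.label(mask, connectivity=2)
    n_frames = image.shape[0]
    events = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        duration = r1 - r0
        if duration < min_duration_frames or (c1 - c0) < min_width:
            continue
        events.append(
            BindingEvent(
                x=int(round(region.centroid[1])),
                start_frame=int(r0),
                duration_frames=int(duration),
                duration_s=duration * kymo.frame_interval,
                left_censored=bool(r0 == 0),
                right_censored=bool(r1 == n_frames),
            )
        )
    events.sort(key=lambda e: (e.start_frame, e.x))
    return events


def censor_filter(
    events: list[BindingEvent], policy: str = "exclude_censored"
) -> list[BindingEvent]:
    """Select events for duration analysis.

    ``exclude_censored`` drops events whose dwell is truncated by either
    movie boundary; ``keep_flagged`` passes everything through with flags
    intact. Censored events still count toward landings (see
    :func:`landing_count`) unless left-censored, since a left-censored
    event's landing was never observed.
    """
    if policy == "keep_flagged":
        return list(events)
    if policy == "exclude_censored":
        return [e for e in events if not e.censored]
    raise ParameterError(f"unknown censor policy {policy!r}")


def dwell_times(events: list[BindingEvent], policy: str = "exclude_censored") -> np.ndarray:
    """Dwell durations (s) of events eligible for survival analysis."""
    return np.array([e.duration_s for e in censor_filter(events, policy)], dtype=float)


def landing_count(events: list[BindingEvent]) -> int:
    """Number of observed landings: every event except left-censored ones."""
    return sum(1 for e in events if not e.left_censored)


def landing_rate(
    event_count: int, fov_area: float, duration: float, concentration: float
) -> float:
    """Normalize an event count per unit area, time and enzyme concentration.

    Returns events / (μm² · s · M), the concentration-independent landing
    rate used to compare on-rates across conditions.
    """
    if event_count < 0:
        raise ParameterError("event_count must be >= 0")
    if fov_area <= 0 or duration <= 0 or concentration <= 0:
        raise ParameterError("fov_area, duration and concentration must be > 0")
    return event_count / (fov_area * duration * concentration)


def aggregate_landing_rates(per_movie_rates) -> LandingRateEstimate:
    """Mean and SEM (sample SD / sqrt(n)) of per-movie normalized rates."""
    rates = np.asarray(list(per_movie_rates), dtype=float)
    if rates.size < 1:
        raise ParameterError("need at least one movie")
    mean = float(rates.mean())
    sem = float(rates.std(ddof=1) / np.sqrt(rates.size)) if rates.size >= 2 else None
    return LandingRateEstimate(
        per_movie_rates=tuple(float(r) for r in rates),
        mean=mean,
        sem=sem,
        n_movies=int(rates.size),
    )
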