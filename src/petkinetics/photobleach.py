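"""Population-level photobleaching of immobilized emitters.

Quantum-dot labels blink and photobleach, which truncates the apparent
durations of irreversibly (nonspecifically) bound particles. The control
analysis here images surface-immobilized emitters under continuous
illumination, extracts the spatial-mean intensity per frame, and fits an
exponential decay; comparing the fitted time constant across laser powers
confirms that a dwell-time component tracking illumination intensity is a
photophysical artifact, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitFailureError, ParameterError, StructuralError
from .kymograph import MovieStack

__all__ = [
    "IntensityTrace",
    "DecayFit",
    "PowerDependence",
    "mean_intensity_trace",
    "fit_intensity_decay",
    "power_dependence",
]


@dataclass(frozen=True)
class IntensityTrace:
    """Per-frame spatial-mean intensity of a movie, with optional laser power (mW)."""

    times: np.ndarray
    mean_intensity: np.ndarray
    laser_power: float | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.mean_intensity):
            raise StructuralError("times and mean_intensity must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise StructuralError("times must be strictly increasing")


@dataclass(frozen=True)
class DecayFit:
    """Exponential-decay fit I(t) = I₀·exp(−t/τ) (+ offset): τ, SE and diagnostics.

    ``unidentifiable`` is set when the decaying amplitude is negligible
    relative to the trace level (e.g. a flat trace fitted with a free
    offset), in which case τ carries no information.
    """

    tau_s: float
    se_tau: float
    amplitude: float
    offset: float
    laser_power: float | None = None
    unidentifiable: bool = False


@dataclass(frozen=True)
class PowerDependence:
    """Bleach time constants ordered by laser power, with pairwise ratios."""

    powers: tuple[float, ...]
    taus: tuple[float, ...]
    decreasing: bool
    ratios: tuple[float, ...]  # tau[i+1] / tau[i] along increasing power


def mean_intensity_trace(movie: MovieStack, dark_value: float = 0.0) -> IntensityTrace:
    """Spatial mean per frame, minus a user-supplied dark/background value."""
    trace = movie.intensity.mean(axis=(1, 2)) - dark_value
    times = np.arange(movie.n_frames) * movie.frame_interval
    return IntensityTrace(times=times, mean_intensity=trace, laser_power=movie.laser_power)


def fit_intensity_decay(trace: IntensityTrace, with_offset: bool = True) -> DecayFit:
    """Least-squares exponential-decay fit of an intensity trace.

    ``with_offset=True`` (default) adds an additive constant to absorb a
    camera baseline. The fitted τ is invariant to scaling the whole trace by
    a positive constant. Raises :class:`FitFailureError` if no positive τ
    can be fitted.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.mean_intensity, dtype=float)
    if t.size < 3:
        raise ParameterError("need at least 3 points to fit a decay")
    span = float(y[0] - y[-1])
    scale = max(abs(float(y.max())), 1e-12)
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-9)

    if with_offset:
        model = lambda tt, i0, tau, c: i0 * np.exp(-tt / tau) + c
        p0 = [span if span != 0 else scale, tau0, float(y[-1])]
        bounds = ([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf])
    else:
        model = lambda tt, i0, tau: i0 * np.exp(-tt / tau)
        p0 = [float(y[0]) if y[0] != 0 else scale, tau0]
        bounds = ([-np.inf, 1e-12], [np.inf, np.inf])

    try:
        popt, pcov = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"intensity-decay fit did not converge: {exc}") from exc
    i0, tau = float(popt[0]), float(popt[1])
    offset = float(popt[2]) if with_offset else 0.0
    if tau <= 0 or i0 < -1e-6 * scale:
        raise FitFailureError("fitted decay is non-positive")
    se_tau = (
        float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    )
    # tau is unconstrained when the decaying amplitude is negligible (a flat
    # trace whose level the free offset absorbs) or when no curvature falls
    # inside the acquisition window.
    unidentifiable = (
        abs(i0) <= 1e-6 * max(abs(i0) + abs(offset), 1e-12)
        or tau > 50.0 * (t[-1] - t[0])
        or not np.isfinite(se_tau)
    )
    return DecayFit(
        tau_s=tau,
        se_tau=se_tau,
        amplitude=i0,
        offset=offset,
        laser_power=trace.laser_power,
        unidentifiable=bool(unidentifiable),
    )


def power_dependence(fits) -> PowerDependence:
    """Check that the bleach time constant shortens as laser power rises.

    ``fits`` is an iterable of ``(laser_power_mW, tau_s)`` pairs; at least
    two powers are required. A truly photophysical truncation clock must
    accelerate (τ must fall) with illumination intensity.
    """
    pairs = sorted((float(p), float(tau)) for p, tau in fits)
    if len(pairs) < 2:
        raise ParameterError("need at least two laser powers")
    powers = tuple(p for p, _ in pairs)
    taus = tuple(tau for _, tau in pairs)
    ratios = tuple(taus[i + 1] / taus[i] for i in range(len(taus) - 1))
    decreasing = all(r < 1.0 for r in ratios)
    return PowerDependence(powers=powers, taus=taus, decreasing=decreasing, ratios=ratios)
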