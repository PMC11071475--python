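"""Kinetic parameters for an enzyme acting on an insoluble surface.

For an interfacial enzyme visualized while bound to its substrate, the
observed dissociation lumps two exits from the bound state: unbinding
without turnover (k_off) and completing catalysis followed by rapid
product release (k_cat). The fast-phase dwell time constant therefore
measures an apparent off-rate

    k_off_app = k_off + k_cat = 1 / τ_fast,

which immediately bounds the turnover rate (k_cat ≤ k_off_app), and each
binding encounter ends productively with probability
p_catalysis = k_cat / (k_cat + k_off). Landing rates are normalized per
unit area, time and enzyme concentration; a corrected landing rate
multiplies the overall rate by the relative fast-phase amplitude, keeping
only the specific (catalytically relevant) fraction of landings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detect import LandingRateEstimate
from .errors import ParameterError
from .survival import ExpFit

__all__ = [
    "RateDecomposition",
    "KineticSummary",
    "ConditionComparison",
    "apparent_off_rate",
    "report_off_rate",
    "catalysis_probability",
    "corrected_landing_rate",
    "compare_conditions",
    "kcat_upper_bound",
    "summarize_condition",
]


@dataclass(frozen=True)
class RateDecomposition:
    """A user-supplied split of the apparent off-rate into k_off and k_cat.

    The single-molecule data alone cannot identify the split; this type
    carries externally supplied decompositions and their encounter
    probabilities. ``p_catalysis + p_unbind == 1`` always.
    """

    k_off: float
    k_cat: float
    p_catalysis: float
    p_unbind: float


@dataclass(frozen=True)
class KineticSummary:
    """Per-condition kinetic readout: dwell constants, off-rate, landing rates."""

    condition: str
    tau_fast: float
    se_tau_fast: float
    tau_slow: float | None
    se_tau_slow: float | None
    amp_fast: float
    k_off_app: float
    landing_rate_mean: float | None
    landing_rate_sem: float | None
    corrected_landing_rate: float | None
    n_movies: int
    n_events: int
    inhibitor_present: bool = False


@dataclass(frozen=True)
class ConditionComparison:
    """Two-sample t-test on per-movie normalized landing rates."""

    t_stat: float
    p_value: float
    n_a: int
    n_b: int
    welch: bool


def apparent_off_rate(tau_fast: float) -> float:
    """Apparent off-rate 1/τ_fast (s⁻¹); see :func:`report_off_rate` for rounding."""
    if tau_fast <= 0:
        raise ParameterError("tau_fast must be > 0")
    return 1.0 / tau_fast


def report_off_rate(tau_fast: float) -> float:
    """1/τ_fast rounded the way such rates are conventionally reported.

    Two decimals, except one decimal when τ_fast < 2 s (where a second
    decimal would overstate the precision of a short, noisy phase):
    τ = 2.7 → 0.37, τ = 4.0 → 0.25, τ = 1.7 → 0.6.
    """
    rate = apparent_off_rate(tau_fast)
    decimals = 1 if tau_fast < 2.0 else 2
    return round(rate, decimals)


def catalysis_probability(k_off: float, k_cat: float) -> RateDecomposition:
    """Partition a binding encounter between catalysis and futile unbinding.

    p_catalysis = k_cat/(k_cat + k_off); p_unbind is its complement
    k_off/(k_cat + k_off).
    """
    if k_off < 0 or k_cat < 0:
        raise ParameterError("rates must be >= 0")
    total = k_off + k_cat
    if total <= 0:
        raise ParameterError("k_off + k_cat must be > 0")
    p_cat = k_cat / total
    return RateDecomposition(
        k_off=float(k_off), k_cat=float(k_cat), p_catalysis=float(p_cat),
        p_unbind=float(1.0 - p_cat),
    )


def corrected_landing_rate(overall: float, amp_fast: float) -> float:
    """Overall landing rate times the relative fast-phase amplitude.

    Scales landings down to the specifically bound fraction; never exceeds
    the overall rate.
    """
    if not 0.0 <= amp_fast <= 1.0:
        raise ParameterError("amp_fast must lie in [0, 1]")
    if overall < 0:
        raise ParameterError("overall landing rate must be >= 0")
    return overall * amp_fast


def compare_conditions(rates_a, rates_b, equal_var: bool = False) -> ConditionComparison:
    """Two-sample t-test (Welch by default) on per-movie normalized rates."""
    a = np.asarray(list(rates_a), dtype=float)
    b = np.asarray(list(rates_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("need at least 2 movies per condition")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return ConditionComparison(
        t_stat=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        welch=not equal_var,
    )


def kcat_upper_bound(k_off_app: float) -> float:
    """Upper bound on the turnover rate implied by the apparent off-rate.

    Since k_off_app = k_off + k_cat and k_off ≥ 0, k_cat cannot exceed
    k_off_app; the bound is tight only if every dissociation is catalytic.
    """
    if k_off_app <= 0:
        raise ParameterError("k_off_app must be > 0")
    return float(k_off_app)


def summarize_condition(
    condition: str,
    fit: ExpFit,
    landing: LandingRateEstimate | None = None,
    inhibitor_present: bool = False,
) -> KineticSummary:
    """Assemble a condition's kinetic summary from its fit and landing estimate."""
    mean = landing.mean if landing is not None else None
    sem = landing.sem if landing is not None else None
    corrected = (
        corrected_landing_rate(mean, fit.amp_fast) if mean is not None else None
    )
    return KineticSummary(
        condition=condition,
        tau_fast=fit.tau_fast,
        se_tau_fast=fit.se_tau_fast,
        tau_slow=fit.tau_slow,
        se_tau_slow=fit.se_tau_slow,
        amp_fast=fit.amp_fast,
        k_off_app=apparent_off_rate(fit.tau_fast),
        landing_rate_mean=mean,
        landing_rate_sem=sem,
        corrected_landing_rate=corrected,
        n_movies=landing.n_movies if landing is not None else 0,
        n_events=fit.n_events,
        inhibitor_present=inhibitor_present,
    )
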