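"""Survival curves and exponential fits: oracles, invariances, model choice."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petkinetics import (
    DegenerateFitWarning,
    SurvivalCurve,
    ParameterError,
    compare_models,
    empirical_survival,
    fit_biexponential,
    fit_biexponential_mle,
    fit_monoexponential,
    fit_monoexponential_mle,
    simulate_competing_rates,
    simulate_dwell_times,
)


class TestEmpiricalSurvival:
    def test_fraction_at_least_definition(self):
        c = empirical_survival([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(c.times, [1, 2, 3, 4])
        np.testing.assert_allclose(c.survival, [1.0, 0.75, 0.5, 0.25])

    def test_all_equal_dwells_single_point(self):
        c = empirical_survival([2.5] * 7)
        np.testing.assert_array_equal(c.times, [2.5])
        np.testing.assert_array_equal(c.survival, [1.0])

    def test_exponential_sample_matches_closed_form(self, rng):
        d = rng.exponential(5.0, 100_000)
        c = empirical_survival(d)
        idx = np.searchsorted(c.times, 5.0)
        assert c.survival[idx] == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            empirical_survival([])
        with pytest.raises(ParameterError):
            empirical_survival([1.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=1, max_size=200))
    def test_survival_is_nonincreasing_and_bounded(self, dwells):
        c = empirical_survival(dwells)
        assert np.all(np.diff(c.survival) <= 0)
        assert np.all((c.survival >= 0) & (c.survival <= 1))
        assert c.survival[0] == 1.0


class TestMonoexponentialFit:
    def test_exact_exponential_recovered_to_numerical_precision(self):
        t = np.linspace(0.0, 15.0, 40)[1:]
        c = SurvivalCurve(times=t, survival=np.exp(-(t - t[0]) / 3.0),
                          n_events=39, min_observable=t[0])
        fit = fit_monoexponential(c)
        assert fit.tau_fast == pytest.approx(3.0, rel=1e-6)

    def test_competing_rates_sample_gives_inverse_summed_rate(self):
        d = simulate_competing_rates(5000, 0.20, 0.17, seed=8)
        fit = fit_monoexponential(empirical_survival(d))
        assert fit.tau_fast == pytest.approx(1.0 / 0.37, rel=0.05)

    def test_agrees_with_sample_mean_mle(self):
        d = simulate_dwell_times(10_000, 5.0, 5.0, 1.0, frame_interval=0.0, seed=9)
        c = empirical_survival(d)
        ls_tau = fit_monoexponential(c).tau_fast
        mle_tau = fit_monoexponential_mle(d, t0=c.min_observable)
        assert ls_tau == pytest.approx(mle_tau, rel=0.03)
        assert ls_tau == pytest.approx(5.0, rel=0.03)

    def test_scale_equivariance(self):
        d = simulate_dwell_times(3000, 4.0, 4.0, 1.0, frame_interval=0.0, seed=10)
        tau1 = fit_monoexponential(empirical_survival(d)).tau_fast
        tau2 = fit_monoexponential(empirical_survival(7.0 * d)).tau_fast
        assert tau2 == pytest.approx(7.0 * tau1, rel=1e-3)


class TestBiexponentialFit:
    def test_recovers_wildtype_like_parameters_within_se(self):
        d = simulate_dwell_times(2000, 2.7, 38.6, 0.7, frame_interval=0.2, seed=11)
        fit = fit_biexponential(
            empirical_survival(d, min_observable=0.2), se_method="bootstrap", n_boot=60
        )
        assert abs(fit.tau_fast - 2.7) < 3 * fit.se_tau_fast
        assert abs(fit.tau_slow - 38.6) < 3 * fit.se_tau_slow
        assert fit.amp_fast == pytest.approx(0.7, abs=0.1)

    def test_pure_monoexponential_data_collapses_with_warning(self):
        t = np.linspace(0.2, 20.0, 60)
        c = SurvivalCurve(times=t, survival=np.exp(-(t - 0.2) / 4.0),
                          n_events=60, min_observable=0.2)
        with pytest.warns(DegenerateFitWarning):
            fit = fit_biexponential(c)
        assert fit.degenerate
        # model collapse: either amplitudes hit a boundary or taus coincide
        collapsed = (
            fit.amp_fast < 0.05
            or fit.amp_fast > 0.95
            or abs(fit.tau_slow - fit.tau_fast) <= 0.05 * fit.tau_slow
        )
        assert collapsed

    def test_ls_agrees_with_mle_oracle_within_5pct(self):
        d = simulate_dwell_times(10_000, 2.0, 20.0, 0.5, frame_interval=0.0, seed=12)
        ls = fit_biexponential(empirical_survival(d))
        amp, tau_f, tau_s = fit_biexponential_mle(d)
        assert ls.tau_fast == pytest.approx(tau_f, rel=0.05)
        assert ls.tau_slow == pytest.approx(tau_s, rel=0.05)
        assert ls.amp_fast == pytest.approx(amp, abs=0.05)

    def test_label_invariance_to_permuted_starting_guesses(self):
        d = simulate_dwell_times(3000, 2.0, 25.0, 0.6, frame_interval=0.2, seed=13)
        c = empirical_survival(d, min_observable=0.2)
        a = fit_biexponential(c, p0=(0.6, 2.0, 25.0))
        b = fit_biexponential(c, p0=(0.4, 25.0, 2.0))
        assert a.tau_fast == pytest.approx(b.tau_fast, rel=1e-3)
        assert a.tau_slow == pytest.approx(b.tau_slow, rel=1e-3)
        assert a.amp_fast == pytest.approx(b.amp_fast, abs=1e-3)
        assert a.tau_fast <= a.tau_slow

    def test_parameter_recovery_and_bootstrap_coverage_over_replicates(self):
        taus, ses = [], []
        for s in range(50):
            d = simulate_dwell_times(2000, 2.7, 38.6, 0.7, 0.2, seed=3000 + s)
            fit = fit_biexponential(
                empirical_survival(d, min_observable=0.2),
                se_method="bootstrap",
                n_boot=40,
            )
            taus.append(fit.tau_fast)
            ses.append(fit.se_tau_fast)
        taus, ses = np.array(taus), np.array(ses)
        assert abs(np.median(taus) - 2.7) < 0.1 * 2.7
        coverage = np.mean(np.abs(taus - 2.7) <= 2 * ses)
        assert coverage >= 0.8

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            fit_biexponential(empirical_survival([1.0, 2.0, 3.0]))


class TestCompareModels:
    def test_well_separated_biexponential_prefers_bi(self):
        d = simulate_dwell_times(4000, 2.0, 20.0, 0.6, frame_interval=0.2, seed=14)
        c = empirical_survival(d, min_observable=0.2)
        mono, bi = fit_monoexponential(c), fit_biexponential(c)
        assert compare_models(mono, bi).preferred == "bi"

    def test_monoexponential_truth_prefers_mono(self, recwarn):
        d = simulate_dwell_times(4000, 5.0, 5.0, 1.0, frame_interval=0.2, seed=15)
        c = empirical_survival(d, min_observable=0.2)
        mono, bi = fit_monoexponential(c), fit_biexponential(c)
        assert compare_models(mono, bi).preferred in ("mono", None)

    def test_identical_fits_no_preference(self):
        d = simulate_dwell_times(500, 3.0, 30.0, 0.5, frame_interval=0.2, seed=16)
        c = empirical_survival(d, min_observable=0.2)
        bi = fit_biexponential(c)
        assert compare_models(bi, bi).preferred is None
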