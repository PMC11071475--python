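"""Streak detection, censoring and landing-rate normalization."""

import numpy as np
import pytest

from petkinetics import (
    DegenerateThresholdError,
    Kymograph,
    ParameterError,
    aggregate_landing_rates,
    censor_filter,
    detect_streaks,
    landing_count,
    landing_rate,
)


def kymo(image, frame_interval=0.2):
    return Kymograph(image=np.asarray(image, dtype=float), frame_interval=frame_interval)


def bright(shape, runs, lo=0.0, hi=10.0):
    """Image of background ``lo`` with (rows, col) runs set to ``hi``."""
    img = np.full(shape, lo)
    for (r0, r1), c in runs:
        img[r0:r1, c] = hi
    return img


class TestDetectStreaks:
    def test_single_streak_duration_and_seconds(self):
        img = bright((20, 20), [((5, 8), 4)])
        events = detect_streaks(kymo(img), threshold_method="absolute", threshold_value=5)
        assert len(events) == 1
        e = events[0]
        assert (e.x, e.start_frame, e.duration_frames) == (4, 5, 3)
        assert e.duration_s == pytest.approx(0.6)
        assert not e.censored

    def test_dark_gap_splits_into_two_events_without_tolerance(self):
        img = bright((20, 10), [((2, 5), 3), ((10, 12), 3)])
        events = detect_streaks(kymo(img), threshold_method="absolute", threshold_value=5)
        assert [(e.start_frame, e.duration_frames) for e in events] == [(2, 3), (10, 2)]

    @pytest.mark.parametrize("gap,expected", [(0, 2), (1, 2), (2, 1), (3, 1)])
    def test_gap_tolerance_bridges_short_gaps_only(self, gap, expected):
        img = bright((20, 10), [((2, 5), 3), ((7, 9), 3)])  # 2-frame gap
        events = detect_streaks(
            kymo(img), threshold_method="absolute", threshold_value=5,
            gap_tolerance_frames=gap,
        )
        assert len(events) == expected
        if expected == 1:
            assert events[0].duration_frames == 7

    def test_eight_connectivity_joins_jittering_streak(self):
        # one-pixel column jitter must not split a single event
        img = np.zeros((10, 10))
        img[2:4, 5] = 10
        img[4:6, 6] = 10
        events = detect_streaks(kymo(img), threshold_method="absolute", threshold_value=5)
        assert len(events) == 1
        assert events[0].duration_frames == 4

    def test_min_duration_and_min_width_filters(self):
        img = bright((20, 10), [((2, 3), 2), ((8, 12), 6)])
        events = detect_streaks(
            kymo(img), threshold_method="absolute", threshold_value=5,
            min_duration_frames=2,
        )
        assert [(e.start_frame, e.duration_frames) for e in events] == [(8, 4)]
        assert not detect_streaks(
            kymo(img), threshold_method="absolute", threshold_value=5, min_width=2
        )

    def test_boundary_events_flagged_censored(self):
        img = bright((12, 8), [((0, 3), 2), ((9, 12), 5), ((5, 7), 6)])
        events = detect_streaks(kymo(img), threshold_method="absolute", threshold_value=5)
        flags = {e.x: (e.left_censored, e.right_censored) for e in events}
        assert flags == {2: (True, False), 5: (False, True), 6: (False, False)}

    def test_constant_image_with_sigma_threshold_is_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            detect_streaks(kymo(np.full((10, 10), 7.0)))

    def test_offset_invariance_of_robust_threshold(self, rng):
        noise = rng.normal(100.0, 5.0, (60, 40))
        noise[10:20, 7] += 200.0
        base = detect_streaks(kymo(noise))
        shifted = detect_streaks(kymo(noise + 1234.5))
        assert base == shifted
        assert len(base) == 1

    def test_noise_only_image_yields_no_events(self, rng):
        # empirical false-positive control at mean + 4 sigma, min 2 frames
        false_events = 0
        for _ in range(20):
            img = rng.normal(100.0, 5.0, (100, 50))
            false_events += len(detect_streaks(kymo(img), min_duration_frames=2))
        assert false_events == 0


class TestCensorFilter:
    def test_policies(self, rng):
        img = bright((12, 8), [((0, 3), 2), ((5, 7), 6)])
        events = detect_streaks(kymo(img), threshold_method="absolute", threshold_value=5)
        kept = censor_filter(events, "exclude_censored")
        assert [e.x for e in kept] == [6]
        assert censor_filter(events, "keep_flagged") == events
        with pytest.raises(ParameterError):
            censor_filter(events, "drop_everything")

    def test_left_censored_events_do_not_count_as_landings(self):
        img = bright((12, 8), [((0, 3), 2), ((5, 7), 6), ((9, 12), 4)])
        events = detect_streaks(kymo(img), threshold_method="absolute", threshold_value=5)
        # right-censored events still landed during the movie
        assert landing_count(events) == 2


class TestLandingRate:
    def test_direct_arithmetic(self):
        # 32 / (6400 um2 * 600 s * 8e-9 M)
        assert landing_rate(32, 6400, 600, 8e-9) == pytest.approx(1041.666, rel=1e-5)

    def test_zero_events_zero_rate(self):
        assert landing_rate(0, 6400, 600, 8e-9) == 0.0

    def test_linear_in_count_inverse_in_denominators(self):
        base = landing_rate(10, 100, 50, 1e-8)
        assert landing_rate(20, 100, 50, 1e-8) == pytest.approx(2 * base)
        assert landing_rate(10, 200, 50, 1e-8) == pytest.approx(base / 2)
        assert landing_rate(10, 100, 100, 1e-8) == pytest.approx(base / 2)
        assert landing_rate(10, 100, 50, 2e-8) == pytest.approx(base / 2)

    def test_invalid_denominators_rejected(self):
        with pytest.raises(ParameterError):
            landing_rate(10, 0, 600, 8e-9)
        with pytest.raises(ParameterError):
            landing_rate(10, 6400, 600, 0)


class TestAggregateLandingRates:
    def test_hand_calculation(self):
        est = aggregate_landing_rates([2.0, 4.0, 6.0])
        assert est.mean == pytest.approx(4.0)
        assert est.sem == pytest.approx(2.0 / np.sqrt(3), rel=1e-6)
        assert est.n_movies == 3

    def test_constant_rates_have_zero_sem(self):
        est = aggregate_landing_rates([5.0, 5.0, 5.0])
        assert (est.mean, est.sem) == (5.0, 0.0)

    def test_single_movie_sem_undefined(self):
        est = aggregate_landing_rates([3.0])
        assert est.mean == 3.0 and est.sem is None
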