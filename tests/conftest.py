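import numpy as np
import pytest

from petkinetics import GroundTruthEvent, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_render_config():
    """Tiny noiseless field of view for exact render→detect round trips."""
    return SimulationConfig(
        fov_width=8.0,
        fov_height=8.0,
        movie_duration=40.0,
        pixel_size=100.0,
        noise_sd=0.0,
        background_mean=100.0,
        spot_amplitude=1000.0,
        landing_rate_norm=0.0,
        seed=1,
    )


@pytest.fixture
def grid_events():
    """Nine well-separated events on a 3x3 spatial grid, staggered in time."""
    events = []
    for k, (ix, iy) in enumerate([(i, j) for i in range(3) for j in range(3)]):
        events.append(
            GroundTruthEvent(
                x=1.5 + 2.5 * ix,
                y=1.5 + 2.5 * iy,
                landing_time=1.0 + 4.0 * k,
                true_dwell=0.5 + 0.17 * k,
                population="specific",
            )
        )
    return events
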