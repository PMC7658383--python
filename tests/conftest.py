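import numpy as np
import pytest

from copgait import GaitParams, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A short default-calibration session with a known lag."""
    return generate_session(GaitParams(n_steps=10, seed=11, lag_frames=17))


@pytest.fixture(scope="session")
def zero_jitter_session():
    """Deterministic session: fixed 120-frame stance, 163-frame cycle, no noise."""
    params = GaitParams(
        n_steps=6,
        seed=5,
        lag_frames=0,
        stance_frames_sd=0.0,
        step_scale_sd=0.0,
        imu_noise_sd=0.0,
    )
    return generate_session(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
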