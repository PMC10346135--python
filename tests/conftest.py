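import numpy as np
import pytest

from kinagree import SimConfig, generate_session, make_template


@pytest.fixture(scope="session")
def hip_template():
    return make_template("hip_flexion")


@pytest.fixture(scope="session")
def clean_session(hip_template):
    """Noise-free, lag-free, offset-free hip-flexion session."""
    cfg = SimConfig(
        template=hip_template,
        mocap_noise_sd=0.0,
        imu_noise_sd=0.0,
        accel_noise_sd=0.0,
        rng_seed=11,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def noisy_session(hip_template):
    """Default-noise session with a 0.5 s lag and a 2 deg inter-system offset."""
    cfg = SimConfig(
        template=hip_template,
        lag=0.5,
        inter_system_offset=2.0,
        rng_seed=7,
    )
    return generate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
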