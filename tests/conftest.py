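import numpy as np
import pytest

from emgknee import GaitSimConfig, simulate_recording


@pytest.fixture(scope="session")
def short_recording():
    """20 s synthetic recording with the default 0.2 s delay."""
    return simulate_recording(GaitSimConfig(duration_s=20.0, delay_s=0.2, seed=7))


@pytest.fixture(scope="session")
def clean_recording(short_recording):
    """Same recording without interference or measurement noise."""
    return simulate_recording(
        GaitSimConfig(duration_s=20.0, delay_s=0.2, seed=7,
                      interference_amp=0.0, noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
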