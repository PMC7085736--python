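import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_sequence():
    """A short noiseless rendered recording with a known 0.25 Hz rate."""
    from depthresp.synth import SENSORS, BreathingProfile, generate_record

    profile = BreathingProfile(rate=0.25, amplitude=6.0, noise_sd=0.0)
    seq, track, ts, clean = generate_record(
        profile, SENSORS["d415"], duration=60.0, events=[], seed=3
    )
    return seq, clean
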