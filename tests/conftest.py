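import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phonoseg import (SimConfig, generate_recording, segment_recording)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def clean_cfg():
    """Noiseless, jitter-free 60-s config: every beat is identical."""
    return SimConfig(duration=60.0, noise_std=0.0, ecg_noise_std=0.0,
                     s1_jitter=0.0, s1_split_jitter=0.0, s2_jitter=0.0,
                     s2_split_jitter=0.0, rr_jitter=0.0, seed=2)


@pytest.fixture(scope="session")
def clean_record(clean_cfg):
    return generate_recording(clean_cfg)


@pytest.fixture(scope="session")
def default_record():
    """Default stated-world record: cohort-mean delays, jitter, ~21 dB SNR."""
    return generate_recording(SimConfig(duration=60.0, seed=1))


@pytest.fixture(scope="session")
def segmented_default(default_record):
    rec, _ = default_record
    return segment_recording(rec)


@pytest.fixture(scope="session")
def segmented_clean(clean_record):
    rec, _ = clean_record
    return segment_recording(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
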