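import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pulseonset import DetectionConfig, detect_pulses, generate_scan
from pulseonset.preprocessing import preprocess

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

FS = 125.0


@pytest.fixture(scope="session")
def config() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture(scope="session")
def clean_scan():
    """Two minutes of clean normal-morphology beats at ~70 bpm."""
    return generate_scan(120.0, hr_mean_bpm=70.0, hr_sd_bpm=3.0,
                         morphology="normal", sampling_rate=FS, seed=7)


@pytest.fixture(scope="session")
def clean_result(clean_scan):
    return detect_pulses(clean_scan.signal)


@pytest.fixture(scope="session")
def clean_filtered(clean_scan, config):
    filtered, mdf = preprocess(clean_scan.signal, config)
    return filtered, mdf


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
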