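import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from trackball import (  # noqa: E402
    KinematicsConfig,
    TrialRecord,
    WalkerParams,
    render_sensor_streams,
    simulate_path,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_truth():
    """A 60-s default-parameter simulated trial (exact path + metrics)."""
    return simulate_path(WalkerParams(), duration_s=60.0, seed=42)


@pytest.fixture(scope="session")
def short_trial(short_truth):
    """The same trial rendered noiselessly as a cumulative-dialect TrialRecord."""
    a, b = render_sensor_streams(short_truth, seed=43)
    return TrialRecord("ind1", 1, a, b)


@pytest.fixture
def unsmoothed_config():
    return KinematicsConfig(smoothing_window=1)
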