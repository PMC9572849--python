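import pytest
from hypothesis import HealthCheck, settings

from pushpull.datasets import load_participants
from pushpull.simulate import SimulationConfig, simulate_mvc_trials, simulate_session

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """A shortened protocol (2 traversals, 3 s legs) for fast unit tests."""
    return SimulationConfig(
        seed=42,
        n_series=1,
        attempts_per_series=2,
        segment_duration_mean=3.0,
        inter_series_pause=5.0,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return simulate_session(small_config)


@pytest.fixture(scope="session")
def small_mvc(small_config):
    return simulate_mvc_trials(small_config)


@pytest.fixture(scope="session")
def cohort_records():
    """The bundled 20-participant characteristics table."""
    return load_participants()
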