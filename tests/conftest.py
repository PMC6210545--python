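import numpy as np
import pytest

from wristfall import AccelTrace, SimSessionConfig, simulate_session


def random_trace(n: int, rate_hz: float = 31.25, seed: int = 0,
                 fall_frac: float = 0.2) -> AccelTrace:
    """A random (unstructured) labeled trace for contract/property tests."""
    rng = np.random.default_rng(seed)
    return AccelTrace(
        t=np.arange(n) / rate_hz,
        acc=rng.normal(0.0, 1.0, size=(n, 3)),
        fall=rng.random(n) < fall_frac,
        rate_hz=rate_hz,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trace():
    return random_trace(200, seed=7)


@pytest.fixture(scope="session")
def session_trace():
    """One synthetic session with falls and ADLs (shared, read-only)."""
    return simulate_session(
        SimSessionConfig(falls_per_type=1, n_adls=6, seed=11)
    )


@pytest.fixture(scope="session")
def training_session():
    """A disjoint-seed session used for fitting detectors."""
    return simulate_session(
        SimSessionConfig(falls_per_type=2, n_adls=10, seed=21)
    )
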