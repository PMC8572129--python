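import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from respireg import PhantomConfig, generate_phantom, respiratory_signal

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: Compact phantom for unit tests: same construction as the default, smaller
#: frame and fewer slices/phases so per-test cost stays low.
SMALL_CONFIG = PhantomConfig(
    image_size=128, n_slices=24, n_phases=6, amplitude_slices=4.0, seed=42
)
#: Mid-lung 1-based slice range of the small phantom (flat lung profile).
SMALL_RANGE = (9, 17)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_phantom(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size phantom under its default study conditions."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def default_signal(default_dataset):
    """Respiratory signal of the default phantom (registers all phases)."""
    return respiratory_signal(default_dataset.volume)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
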