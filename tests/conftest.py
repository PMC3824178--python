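import numpy as np
import pytest

from vepcasl import AcquisitionTiming, make_phantom


@pytest.fixture(scope="session")
def timing() -> AcquisitionTiming:
    return AcquisitionTiming()


@pytest.fixture(scope="session")
def small_timing() -> AcquisitionTiming:
    return AcquisitionTiming(n_slices=8)


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced-grid phantom shared across tests (deterministic, seed 0)."""
    return make_phantom(shape=(32, 32, 8), seed=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
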