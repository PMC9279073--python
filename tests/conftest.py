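import numpy as np
import pytest

from vesselfuse import PhantomConfig, build_network, generate_phantom


@pytest.fixture(scope="session")
def default_model():
    """One default-config network shared by read-only shape tests."""
    return build_network(seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    """A 128x128 phantom pair used across data-path tests."""
    return generate_phantom(PhantomConfig(size=(128, 128), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
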