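import numpy as np
import pytest

from nodulekit.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def sample(phantom_config):
    """One default phantom with a single nodule."""
    return generate_phantom(phantom_config, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
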