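import numpy as np
import pytest

from polypssl.fixtures import FixtureConfig, generate_fixture_set
from polypssl.model import ModelConfig, build_model


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(backbone="tiny", levels=3, base_channels=4, input_size=(32, 32))


@pytest.fixture(scope="session")
def tiny_net(tiny_config):
    return build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def small_fixture_set():
    return generate_fixture_set(FixtureConfig(n_images=8, image_size=(32, 32), seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
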