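import numpy as np
import pytest
from hypothesis import settings

from ifnkin.network import RateConstants, build_network
from ifnkin.synth import GeneratorConfig, generate_viperin_dataset

settings.register_profile("default", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def network():
    return build_network("M3")


@pytest.fixture(scope="session")
def params():
    return RateConstants()


@pytest.fixture(scope="session")
def dense_times():
    return np.linspace(0.0, 24.0, 121)


@pytest.fixture(scope="session")
def small_dataset():
    """Low-noise two-dose dataset shared by estimation tests."""
    config = GeneratorConfig(seed=7, cv=0.05, doses_I=(0.033, 0.33),
                             doses_III=(0.137, 13.7))
    return generate_viperin_dataset(config)
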