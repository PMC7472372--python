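import numpy as np
import pytest

from fixmon import AcquisitionConfig, SyntheticScenario


@pytest.fixture
def config() -> AcquisitionConfig:
    return AcquisitionConfig()


@pytest.fixture
def scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=12345)


@pytest.fixture
def quiet_scenario() -> SyntheticScenario:
    """Noise-free scenario for exact oracle checks."""
    return SyntheticScenario(
        seed=12345, noise_sd_per_cell=0.0, noise_sd_in_vivo_sum=0.0
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)
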