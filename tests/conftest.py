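import numpy as np
import pytest

from nitrophys import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noiseless_cfg():
    """Default experiment with all stochastic components switched off."""
    zero_sigma = {t: (0.0, 0.0) for t in synthdata.TRAIT_CELL_MEANS}
    return synthdata.SimConfig(
        seed=0, sigma=zero_sigma, light_noise_sd=0.0, aci_noise_sd=0.0
    )


@pytest.fixture
def default_cfg():
    return synthdata.SimConfig(seed=42)
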