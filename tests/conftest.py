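import numpy as np
import pytest

from tcrbind import (EncoderConfig, PMHCEncoder, default_pmhc_config,
                     init_encoder)

TINY = dict(n_layers=2, dim=64, n_heads=4, ff_dim=256)


@pytest.fixture(scope="session")
def tiny_tcr_config():
    return EncoderConfig(**TINY)


@pytest.fixture(scope="session")
def tiny_pmhc_config():
    return default_pmhc_config(**TINY)


@pytest.fixture(scope="session")
def tcr_encoder(tiny_tcr_config):
    """Randomly initialised TCR encoder (structure tests only)."""
    return init_encoder(tiny_tcr_config, seed=12345)


@pytest.fixture(scope="session")
def pmhc_encoder(tiny_pmhc_config):
    return PMHCEncoder(tiny_pmhc_config, seed=54321)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
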