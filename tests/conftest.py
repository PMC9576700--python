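import numpy as np
import pytest

from meaburst import NetworkConfig, NeuronParameters, genotype_fixture
from meaburst.experiments import scaled_config


@pytest.fixture(scope="session")
def wt_params() -> NeuronParameters:
    return genotype_fixture("WT").params


@pytest.fixture(scope="session")
def tiny_config() -> NetworkConfig:
    """A seconds-long miniature network run for fast unit tests."""
    return scaled_config(seed=11, n_neurons=50, duration=5.0)


@pytest.fixture(scope="session")
def wt_scaled_raster(wt_params):
    """One scaled WT-network simulation shared across tests."""
    from meaburst import simulate

    return simulate(scaled_config(seed=0), wt_params)
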