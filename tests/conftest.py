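import numpy as np
import pytest

import thetachain as tc
from thetachain.energy import ChainEnergyModel
from thetachain.sampler import SimulationConfig, PartitionSet


@pytest.fixture(scope="session")
def toy_ff():
    return tc.toy_forcefield()


@pytest.fixture(scope="session")
def c27_ff():
    return tc.charmm27_forcefield()


@pytest.fixture(scope="session")
def model_cache(toy_ff):
    cache = {}

    def get(chain: str) -> ChainEnergyModel:
        if chain not in cache:
            topo = tc.build_topology(chain, toy_ff)
            cache[chain] = ChainEnergyModel(topo, toy_ff)
        return cache[chain]

    return get


@pytest.fixture(scope="session")
def toy_partitions(model_cache):
    """Partitions of the 8:0 toy chain shared by sampler tests."""
    m = model_cache("8:0")
    return PartitionSet(m, temperature=303.0, grid_step=7.2, n=30)


def make_config(**kw):
    base = dict(temperature=303.0, samples=20_000, grid_step=7.2,
                subdivisions=30, seed=1)
    base.update(kw)
    return SimulationConfig(**base)
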