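import numpy as np
import pytest

from asarscan.simulate import SimulationConfig, simulate_annotation


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(master_seed=11)


@pytest.fixture(scope="session")
def annotation(sim_config):
    """One shared synthetic annotation (genes + exons + L1 repeats)."""
    return simulate_annotation(sim_config, seed=11)


@pytest.fixture(scope="session")
def focal_domain(sim_config):
    """The planted expressed, L1-rich ~185 kb domain."""
    return next(d for d in sim_config.domains if d.l1_target is not None)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
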