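import numpy as np
import pytest

from cotarget_atlas import synthetic_data as sd


@pytest.fixture(scope="session")
def sim_cfg() -> sd.SimConfig:
    """Default study-condition configuration with a fixed seed."""
    return sd.SimConfig(rng_seed=11)


@pytest.fixture(scope="session")
def catalog(sim_cfg):
    return sd.simulate_mirna_catalog(sim_cfg)


@pytest.fixture(scope="session")
def simulated_sites(sim_cfg, catalog):
    return sd.simulate_sites_and_conservation(sim_cfg, catalog)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=length))
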