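import numpy as np
import pytest

from samirnet.datasets import load_sa_mirna_targets
from samirnet.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def table1():
    """Published SA-miRNA target table (8 blocks, 558 rows)."""
    return load_sa_mirna_targets()


@pytest.fixture(scope="session")
def sim_bundle():
    """One medium synthetic study shared across tests."""
    return simulate_all(SimulationConfig(rng_seed=20260920))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
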