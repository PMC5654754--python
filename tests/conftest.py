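import numpy as np
import pytest

from adabf import simpop


@pytest.fixture(scope="session")
def pool():
    """One default haplotype pool (10,000 haplotypes, 150 sites)."""
    return simpop.make_pool(seed=2024)


@pytest.fixture(scope="session")
def pools():
    """Several pools, as the benchmark experiments rotate regions."""
    return [simpop.make_pool(seed=3000 + i) for i in range(5)]


@pytest.fixture(scope="session")
def trio_dataset(pool):
    """A null 200-trio dataset from the shared pool."""
    cfg = simpop.SimConfig(design="trio", n_trios=200, d=0)
    return simpop.simulate_trios(pool, cfg, rng=77)


@pytest.fixture(scope="session")
def cc_dataset(pool):
    """A null 300+300 case-control dataset from the shared pool."""
    cfg = simpop.SimConfig(design="cc", n_cases=300, n_controls=300, d=0)
    return simpop.simulate_case_control(pool, cfg, rng=78)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
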