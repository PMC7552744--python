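import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amplityper.allele_calling import AlleleRegistry
from amplityper.synthetic_data import SimConfig, make_allele_pool, simulate_genotypes

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg() -> SimConfig:
    """Study-scale defaults with a fixed seed."""
    return SimConfig(rng_seed=20)


@pytest.fixture(scope="session")
def pool(cfg):
    return make_allele_pool(cfg, cfg.rng())


@pytest.fixture(scope="session")
def genotypes(cfg, pool):
    rng = np.random.default_rng(21)
    return simulate_genotypes(cfg, pool, rng)


@pytest.fixture()
def registry(pool) -> AlleleRegistry:
    return AlleleRegistry(list(pool.sequences.items()))


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    """Short alleles and shallow coverage for fast unit-level simulations."""
    return SimConfig(
        n_alleles=4,
        allele_length=60,
        n_variable_sites=10,
        allele_frequencies=(0.4, 0.3, 0.2, 0.1),
        n_individuals=6,
        coverage_range=(100, 200),
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_pool(tiny_cfg):
    return make_allele_pool(tiny_cfg, tiny_cfg.rng())
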