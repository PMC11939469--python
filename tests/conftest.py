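import numpy as np
import pytest

from ovifeed import derive_phenotypes, simulate_flock, simulate_genotypes
from ovifeed.sim import SimConfig


@pytest.fixture(scope="session")
def base_flock():
    """One default-conditions flock shared by read-only tests."""
    G = simulate_genotypes(81, 300, 26, seed=11)
    return simulate_flock(G, SimConfig(n_snps=300), seed=12)


def derive_period(flock, period_name: str, dm_fraction: float):
    return derive_phenotypes(
        flock.weights[period_name],
        flock.intakes[period_name],
        start_day=0,
        end_day=42,
        dm_fraction=dm_fraction,
        covariates=flock.covariates,
    )


@pytest.fixture(scope="session")
def pheno_p1(base_flock):
    return derive_period(base_flock, "period1", 0.906)


@pytest.fixture(scope="session")
def pheno_p2(base_flock):
    return derive_period(base_flock, "period2", 0.897)


@pytest.fixture()
def rng():
    return np.random.default_rng(2021)
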