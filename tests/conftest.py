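import numpy as np
import pytest

from fnfiber import (
    DomainParams,
    DomainTable,
    ThermalContext,
    default_domain_table,
)


@pytest.fixture(scope="session")
def ctx():
    return ThermalContext()


@pytest.fixture(scope="session")
def table():
    return default_domain_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_uniform_table(k0: float, delta_x: float = 0.4, n_types: int = 15) -> DomainTable:
    """A table where every domain type shares one (k0, delta_x) pair."""
    params = {
        f"type-{i}": DomainParams(f"type-{i}", k0, delta_x) for i in range(n_types)
    }
    return DomainTable(params=params)


@pytest.fixture(scope="session")
def dead_table():
    """Unfolding effectively disabled (k0 so small no event ever fires)."""
    return make_uniform_table(1e-300)


@pytest.fixture(scope="session")
def hot_table():
    """Fast unfolding for short stochastic tests."""
    return make_uniform_table(5.0)
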