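import numpy as np
import pytest

from sundiv.census import table1_fixture
from sundiv.diversity import Metacommunity, build_metacommunity
from sundiv.synthetic import ScenarioConfig, simulate_scenario


@pytest.fixture(scope="session")
def fixture_table():
    """The packaged zone-level abundance-table census (2 years, 3 zones)."""
    return table1_fixture()


@pytest.fixture(scope="session")
def small_scenario_table():
    """A compact stationary synthetic network for structural tests."""
    cfg = ScenarioConfig(
        n_plots=33, zone_split=(15, 9, 9), extent=(3000.0, 1200.0), seed=11
    )
    return simulate_scenario(cfg)


def random_metacommunity(rng: np.random.Generator, S: int = 6, J: int = 5,
                         zero_frac: float = 0.3) -> Metacommunity:
    """Random sparse metacommunity with no empty rows or columns."""
    while True:
        m = rng.random((S, J))
        m[rng.random((S, J)) < zero_frac] = 0.0
        if (m.sum(axis=0) > 0).all() and (m.sum(axis=1) > 0).all():
            return build_metacommunity(m)


@pytest.fixture
def mc_factory():
    return random_metacommunity
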