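import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import utilmap as um
from utilmap.value_sets import Crosswalk, Tariff3L

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_tariff():
    """Constant 0.1, every level-2 decrement 0.05, level-3 0.2, N3 0.3."""
    dec = {}
    for code in ("mo", "sc", "ua", "pd", "ad"):
        dec[(code, 2)] = 0.05
        dec[(code, 3)] = 0.2
    return Tariff3L(constant=0.1, decrements=dec, n3=0.3, label="toy")


@pytest.fixture(scope="session")
def toy_crosswalk():
    """Every 5L state maps to 1 - (sum of levels)/25; (5,...,5) -> 0."""
    import itertools

    table = {
        "".join(map(str, s)): 1.0 - sum(s) / 25.0
        for s in itertools.product(range(1, 6), repeat=5)
    }
    return Crosswalk(table=table, label="toy")


@pytest.fixture(scope="session")
def uk_crosswalk():
    return um.synthetic_uk_crosswalk()


@pytest.fixture(scope="session")
def sim_small():
    """120 subjects x 3 visits with ground truth; shared across tests."""
    return um.simulate_dataset(um.SimConfig(n_subjects=120, seed=7))


@pytest.fixture(scope="session")
def table_small(sim_small):
    observations, _ = sim_small
    return um.assemble_scenario(
        observations, um.Scenario("self", "self", include_item7=False, include_age_sex=True)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
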