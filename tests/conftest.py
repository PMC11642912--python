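import numpy as np
import pytest

from apcmort import (CoverageFactors, LexisTable, SyntheticScenario,
                     build_lexis, correct_records, degrade_records,
                     simulate_scenario)
from apcmort.synthetic import coverage_factors_frame


@pytest.fixture(scope="session")
def scenario():
    """Default study conditions, fixed seed."""
    return SyntheticScenario(seed=20240301 % (2**31))


@pytest.fixture(scope="session")
def simulated(scenario):
    return simulate_scenario(scenario)


@pytest.fixture(scope="session")
def degraded(simulated, scenario):
    records, _ = simulated
    return degrade_records(records, scenario)


@pytest.fixture(scope="session")
def corrected(degraded, scenario):
    factors = CoverageFactors.from_frame(coverage_factors_frame(scenario))
    return correct_records(degraded, factors, external_fraction=1.0)


@pytest.fixture(scope="session")
def lexis(corrected, simulated, scenario):
    _, pop = simulated
    return build_lexis(corrected, pop, scenario.mechanism)


@pytest.fixture
def toy_lexis():
    """3 ages x 3 periods with hand-set counts for oracle comparisons."""
    deaths = np.array([[4.0, 6, 9], [10, 14, 13], [20, 25, 31]])
    py = np.full((3, 3), 1e5)
    return LexisTable(deaths, py,
                      age_labels=["a1", "a2", "a3"],
                      period_labels=["p1", "p2", "p3"],
                      cohort_labels=["c1", "c2", "c3", "c4", "c5"])
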