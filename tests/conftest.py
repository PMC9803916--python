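import numpy as np
import pytest

from radstox.simulate import (
    SimulationConfig,
    fixture_cohort_from_printed_counts,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 51-patient cohort built from the printed counts."""
    return fixture_cohort_from_printed_counts()


@pytest.fixture(scope="session")
def small_simulated_cohort():
    """A small synthetic cohort under default study conditions."""
    return simulate_cohort(SimulationConfig(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
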