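import numpy as np
import pytest

from censmed import (
    MediationDataset,
    SimulationScenario,
    calibrate_censoring,
    sample_case_control,
    simulate_population,
)


@pytest.fixture(scope="session")
def cont_scenario():
    """Continuous-outcome scenario: MAF 0.3, a = b = 0.4, ~39% censoring."""
    sc = SimulationScenario(
        maf=0.3, a0=6.0, a=0.4, b0=1.0, b=0.4, c=0.5,
        family="continuous", censoring=0.39, n=1000,
    )
    calibrate_censoring(sc, seed=101)
    return sc


@pytest.fixture(scope="session")
def binary_scenario():
    """Binary case-control scenario: a = b = 0.4, ~20% censoring, ~30% prevalence."""
    sc = SimulationScenario(
        maf=0.3, a0=6.0, a=0.4, b0=-3.7, b=0.4, c=0.5,
        family="binary", censoring=0.20, n=None, n_case=500, n_control=500,
    )
    calibrate_censoring(sc, seed=102)
    return sc


@pytest.fixture(scope="session")
def cont_data(cont_scenario):
    """One n=400 draw from the continuous scenario (seeded)."""
    return simulate_population(cont_scenario, 400, seed=7)


@pytest.fixture(scope="session")
def binary_data(binary_scenario):
    """One 250/250 case-control draw with sampling weights (seeded)."""
    pop = simulate_population(binary_scenario, 20_000, seed=8)
    return sample_case_control(
        pop, 250, 250, binary_scenario.attained_prevalence, seed=9
    )


@pytest.fixture()
def toy_dataset():
    """Six subjects, one censored, two exposure groups, unit weights."""
    return MediationDataset(
        outcome=np.array([1.2, 0.7, 2.1, 1.5, 0.9, 1.8]),
        mediator_time=np.array([2.0, 3.0, 5.0, 4.0, 6.0, 7.0]),
        event=np.array([1, 1, 0, 1, 1, 1]),
        exposure=np.array(["low", "high", "low", "high", "low", "high"]),
        family="continuous",
    )
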