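import numpy as np
import pytest

from stressnet import (
    FULL_STRESS,
    SpeciesState,
    apply_intervention,
    apply_stress,
    default_formulation,
    generate_population,
    healthy_parameters,
    healthy_state_array,
    simulate_population,
    steady_state,
)


@pytest.fixture(scope="session")
def healthy_params():
    return healthy_parameters()


@pytest.fixture(scope="session")
def healthy_state():
    return SpeciesState.from_array(healthy_state_array())


@pytest.fixture(scope="session")
def formulation():
    return default_formulation()


@pytest.fixture(scope="session")
def stressed_params(healthy_params):
    return apply_stress(healthy_params, FULL_STRESS)


@pytest.fixture(scope="session")
def stressed_ss(stressed_params, healthy_state):
    return steady_state(stressed_params, guess=healthy_state)


@pytest.fixture(scope="session")
def combined_params(stressed_params, formulation):
    return apply_intervention(stressed_params, formulation)


@pytest.fixture(scope="session")
def combined_ss(combined_params, healthy_state):
    return steady_state(combined_params, guess=healthy_state)


@pytest.fixture(scope="session")
def study(healthy_params, formulation):
    """The default in-silico study: 1000 individuals, stressed and
    combined-intervention arms (paired)."""
    pop = generate_population(1000, 1)
    result = simulate_population(
        pop, arms=[("stressed", None), ("combined", formulation)],
        params=healthy_params,
    )
    return {"population": pop, "result": result}
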