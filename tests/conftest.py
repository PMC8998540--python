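import pytest

from equisim.cohort import (
    CohortParams,
    assign_networks,
    build_da_lookup,
    generate_cohort,
    generate_das,
)
from equisim.depression import CoefficientSet


@pytest.fixture(scope="session")
def small_params():
    return CohortParams(n_agents=600, n_das=12, seed=3)


@pytest.fixture(scope="session")
def small_population(small_params):
    das = generate_das(small_params)
    agents = assign_networks(generate_cohort(das, small_params), small_params)
    return das, agents


@pytest.fixture(scope="session")
def default_coeffs():
    return CoefficientSet()


@pytest.fixture(scope="session")
def default_population():
    """Full-size default population (session-scoped: generated once)."""
    params = CohortParams(seed=1)
    das = generate_das(params)
    agents = assign_networks(generate_cohort(das, params), params)
    return params, das, agents


@pytest.fixture()
def da_lookup(small_population):
    das, _ = small_population
    return build_da_lookup(das)
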