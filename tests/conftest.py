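import numpy as np
import pytest

from cobenefit import (
    ScenarioConfig,
    SpeciesMap,
    build_operators,
    generate_scenario,
)


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """10x10 desk scenario used by most integration-level tests."""
    return ScenarioConfig(seed=7, nrows=10, ncols=10, n_provinces=3, cities_per_province=2)


@pytest.fixture(scope="session")
def small_scenario(small_config):
    """(domain, regions, pop, catalog, inventory, ier, baseline, met) bundle."""
    return generate_scenario(small_config)


@pytest.fixture(scope="session")
def small_operators(small_scenario):
    domain, *_, met = small_scenario
    return build_operators(domain, met)


@pytest.fixture(scope="session")
def species_map() -> SpeciesMap:
    return SpeciesMap()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
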