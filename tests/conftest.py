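import numpy as np
import pandas as pd
import pytest

from funcdyn import (
    SimulationConfig,
    TraitTable,
    build_trait_space,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_trait_table(n_species: int, seed: int = 0) -> TraitTable:
    """Small random but deterministic trait table for unit tests."""
    rng = np.random.default_rng(seed)
    species = [f"s{i}" for i in range(n_species)]
    categories = {}
    for name, k in (("diet", 4), ("stratum", 3)):
        rows = rng.dirichlet(np.ones(k), size=n_species)
        categories[name] = pd.DataFrame(
            rows, index=species, columns=[f"{name}{j}" for j in range(k)]
        )
    biomass = pd.Series(
        10 ** rng.uniform(0.7, 2.4, size=n_species), index=species, name="biomass_g"
    )
    return TraitTable(species, categories, biomass)


@pytest.fixture
def toy_traits():
    return make_trait_table(4, seed=3)


@pytest.fixture
def small_fd():
    """Functional dissimilarity over a 5-species pool."""
    return build_trait_space(make_trait_table(5, seed=11))


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study dataset (13 species, 19 years)."""
    return simulate_dataset(SimulationConfig(seed=7))
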