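import numpy as np
import pandas as pd
import pytest

from woodgrad.fieldcalc import process_tables
from woodgrad.synthgen import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A modest campaign: 200 trees, 25 species, 4 sites, default gradients."""
    return SimulationConfig(n_trees=200, n_species=25, n_sites=4, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def processed(small_dataset):
    """(compartments_df, trees_df) after the field-calculation chain."""
    comp, trees = process_tables(
        small_dataset["samples"], small_dataset["logs"], small_dataset["trees"]
    )
    trees = trees.merge(
        small_dataset["species"][["species_id", "WD_GWD", "guild"]], on="species_id"
    )
    return comp, trees


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
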