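import logging

import numpy as np
import pytest

from pollentraits.alignment import build_environment
from pollentraits.community import build_cwm_series
from pollentraits.simulate import (
    SimulationConfig,
    simulate_dataset,
    table_direction_effects,
)
from pollentraits.traits import aggregate_traits

logging.getLogger("pollentraits").setLevel(logging.ERROR)


def small_config(seed: int = 42, **overrides) -> SimulationConfig:
    """A reduced synthetic study: quick to generate, same structure as the default."""
    kw = dict(
        n_samples=30,
        span_years=2100.0,
        n_genera=15,
        n_tree_families=5,
        grains_per_sample=300,
        n_d18o=60,
        n_charcoal=80,
        n_bandwidth=40,
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config(interaction_coefficients=table_direction_effects(0.5)))


@pytest.fixture(scope="session")
def small_environment(small_dataset):
    ds = small_dataset
    return build_environment(ds.record, ds.d18o, ds.charcoal, ds.bandwidth)


@pytest.fixture(scope="session")
def small_trait_table(small_dataset):
    return aggregate_traits(small_dataset.species_records, small_dataset.record.taxa, "genus_only")


@pytest.fixture(scope="session")
def small_cwm(small_dataset, small_trait_table):
    return build_cwm_series(small_dataset.record, small_trait_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
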