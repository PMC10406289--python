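"""Shared fixtures: phantoms, a reduced-grid campaign table, trained surrogates."""

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrseqopt import dataset, surrogate

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantoms():
    return dataset.default_phantoms()


@pytest.fixture(scope="session")
def small_grid_cfg():
    return dataset.small_grid_config()


@pytest.fixture(scope="session")
def small_table(phantoms, small_grid_cfg) -> pd.DataFrame:
    """Campaign table of the reduced 16 x 16 grid (the end-to-end study size)."""
    specs = dataset.build_grid(small_grid_cfg)
    return dataset.run_campaign(specs, phantoms, seed=7)


@pytest.fixture(scope="session")
def split_table(small_table) -> pd.DataFrame:
    return dataset.split(small_table, seed=7)


@pytest.fixture(scope="session")
def trained_models(split_table):
    """Surrogates tuned with a reduced random-search budget."""
    space = surrogate.HyperparameterSpace(budget=12)
    return surrogate.select_and_validate(split_table, space, seed=7)
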