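import datetime as dt

import pandas as pd
import pytest

from hsb import build_cohort, default_catalogue, toy_codelists
from hsb.simulate import SimulationConfig, default_marker_params, simulate

INDEX = dt.date(2019, 9, 1)


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def codelists():
    return toy_codelists()


@pytest.fixture(scope="session")
def small_sim():
    """A 2000-patient synthetic dataset shared across tests.

    broad_code_prob > 0 so narrow vs broad ascertainment genuinely
    differs; default cross-sex leak and noise are on.
    """
    cfg = SimulationConfig(n_patients=2000, seed=42, broad_code_prob=0.2)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    return build_cohort(small_sim.patients)


@pytest.fixture()
def toy_patients():
    """Hand-built patient table: ages 74, 66, 65 plus one late registrant."""
    return pd.DataFrame({
        "patient_id": ["a", "b", "c", "d"],
        "year_of_birth": [1945, 1953, 1954, 1939],
        "sex": ["female", "male", "female", "male"],
        "reg_start": [dt.date(2000, 1, 1), dt.date(2010, 6, 15),
                      dt.date(2005, 3, 1), dt.date(2019, 3, 1)],
    })


def strict_config(n_patients: int, seed: int, **kw) -> SimulationConfig:
    """Config with cross-sex leak 0 (opposite-sex prevalence exactly zero)."""
    return SimulationConfig(
        n_patients=n_patients, seed=seed,
        marker_params=default_marker_params(cross_sex_leak=0.0), **kw)
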