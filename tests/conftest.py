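import numpy as np
import pandas as pd
import pytest

from decanal.synthetic_data import SimulationConfig, simulate_survey


@pytest.fixture(scope="session")
def decanalized_survey():
    """Moderately decanalized draw shared across tests (gamma=0.5, n=4000)."""
    return simulate_survey(SimulationConfig(n_individuals=4000, gamma=0.5, seed=42))


@pytest.fixture(scope="session")
def null_survey():
    """Homoskedastic draw (gamma=0) shared across tests."""
    return simulate_survey(SimulationConfig(n_individuals=4000, gamma=0.0, seed=42))


@pytest.fixture()
def tiny_table():
    """Hand-written 10-row survey table with two incomplete rows."""
    rng = np.random.default_rng(0)
    table, _ = simulate_survey(SimulationConfig(n_individuals=10, gamma=0.0, seed=7))
    table = table.copy()
    table.loc[2, "income"] = np.nan
    table.loc[5, "salt"] = np.nan
    return table
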