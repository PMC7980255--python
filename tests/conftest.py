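import numpy as np
import pytest

from superstruct import (
    LocalizationTable,
    SimulationConfig,
    build_epsilon_grid,
    simulate_dataset,
    superstructure_curve,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def standard_sim():
    """One standard connected-cluster dataset (pr=0.004, defaults)."""
    return simulate_dataset(SimulationConfig(pr_nominal=0.004, seed=71))


@pytest.fixture(scope="session")
def unconnected_sim():
    """One unconnected dataset (pr=0, defaults)."""
    return simulate_dataset(SimulationConfig(pr_nominal=0.0, seed=72))


@pytest.fixture(scope="session")
def standard_curve(standard_sim):
    grid = build_epsilon_grid([(0, 400, 2)])
    return superstructure_curve(standard_sim.table, grid, engine="mst")


@pytest.fixture()
def random_table(rng):
    return LocalizationTable.from_xy(rng.uniform(0, 1000, size=(200, 2)))
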