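import numpy as np
import pytest

import telemap as tm


@pytest.fixture(scope="session")
def lattice_3x3():
    return tm.generate_grid_lattice(3, 3, seed=7)


@pytest.fixture(scope="session")
def adjacency_3x3(lattice_3x3):
    return tm.queen_adjacency(lattice_3x3)


@pytest.fixture(scope="session")
def small_panel_and_adjacency():
    """A 6x6 simulated panel with its adjacency, reused by summary tests."""
    lattice = tm.generate_grid_lattice(6, 6, seed=11)
    cfg = tm.SimulationConfig(n_rows=6, n_cols=6, seed=11)
    adjacency = tm.queen_adjacency(lattice)
    panel = tm.simulate_area_panel(lattice, cfg, ["x1", "x2"], adjacency=adjacency)
    return panel, adjacency


@pytest.fixture(scope="session")
def small_samples(small_panel_and_adjacency):
    panel, adjacency = small_panel_and_adjacency
    spec = tm.ModelSpec(("x1", "x2"), True, True, "full")
    mcmc = tm.McmcConfig(n_iterations=6000, n_burnin=2000, seed=5)
    return tm.fit_bym_poisson(panel, adjacency, spec, tm.Priors(), mcmc)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
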