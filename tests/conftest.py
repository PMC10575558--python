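import numpy as np
import pytest

from triconf import NoiseModel, SignalGrid, default_design


@pytest.fixture(scope="session")
def grid():
    return SignalGrid()


@pytest.fixture(scope="session")
def tiny_grid():
    # two values per axis -> 8 triplets, small enough for exhaustive oracles
    return SignalGrid(0.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def unit_noise():
    return NoiseModel(1.0)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def table1_sims(grid, unit_noise):
    """Whole-grid simulations of all four models on a shared percept stream.

    Session-scoped because several effect-size and selection checks reuse
    the same (fairly expensive) simulation.
    """
    from triconf import simulate_all_models

    return simulate_all_models(grid, unit_noise, n_trials=2000, seed=0)
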