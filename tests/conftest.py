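"""Shared fixtures: the heavy virtual-experiment runs are session-scoped so
the replicate ensembles are simulated once and reused across tests."""

import numpy as np
import pytest
from hypothesis import settings

from epibend.experiments import run_control, run_gamma_sweep, run_mmc

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

MASTER_SEED = 1
GAMMA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


@pytest.fixture(scope="session")
def control_result():
    """Ten developmental control replicates (20 → 100 cells, stalling region
    active, τ_div redraws)."""
    return run_control(replicates=10, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def mmc_result():
    """Ten cycle-arrest replicates (arrest after t=700, evaluated at 1300)."""
    return run_mmc(replicates=10, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def gamma_sweep_result():
    """γ sweep over the five-point grid, ten replicates each."""
    return run_gamma_sweep(GAMMA_GRID, replicates=10, seed=MASTER_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
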