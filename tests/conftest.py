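import numpy as np
import pytest

from oculoforage.fitting import compute_grid_summaries

# Fixed seed for the shared grid cache: the 75-bin summary matrix is a pure
# function of (n_sim_trials, seed), so every fitting test can reuse it.
GRID_SEED = 7
GRID_SIM_TRIALS = 500


@pytest.fixture(scope="session")
def grid500():
    """500-trial-per-point summaries for all 6,120 grid parameter sets."""
    return compute_grid_summaries(n_sim_trials=GRID_SIM_TRIALS, seed=GRID_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
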