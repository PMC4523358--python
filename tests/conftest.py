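import sys
from pathlib import Path

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")
sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import seedpassage as sp
from seedpassage.inference import desk_settings, run_mcmc


@pytest.fixture(scope="session")
def collection_grid():
    return sp.build_observation_grid(54, 3, 24, 6)


@pytest.fixture(scope="session")
def presets():
    return sp.reference_parameter_presets()


@pytest.fixture(scope="session")
def fixture_sim():
    """The packaged synthetic fixture: full default design at the presets."""
    return sp.simulate_dataset(seed=42)


@pytest.fixture(scope="session")
def fixture_fit(fixture_sim):
    """Desk-scale full-model fit of the fixture (shared; ~40 s once)."""
    draws = run_mcmc(fixture_sim.dataset, None, desk_settings(seed=7))
    return draws


@pytest.fixture(scope="session")
def re_free_sim():
    """Default design simulated without random effects: data drawn exactly
    from the model the desk-scale fit assumes (for calibration checks)."""
    params = sp.reference_parameter_presets(sigma_e=0.0, sigma_d=0.0, sigma_g=0.0)
    return sp.simulate_dataset(params=params, seed=43)


@pytest.fixture(scope="session")
def re_free_fit(re_free_sim):
    return run_mcmc(re_free_sim.dataset, None, desk_settings(seed=8))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
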