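import logging
import warnings

import numpy as np
import pytest

from papiokit import SimulationConfig, simulate_population
from papiokit.dataset import analysis_cohort
from papiokit.sociality import compute_dsi

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")
logging.getLogger("papiokit").setLevel(logging.ERROR)


def small_config(seed: int = 1, n_females: int = 40, n_groups: int = 4
                 ) -> SimulationConfig:
    """A reduced-scale configuration for fast unit tests."""
    return SimulationConfig(seed=seed, n_females=n_females, n_groups=n_groups)


@pytest.fixture(scope="session")
def small_sim():
    """One reduced-scale simulated population (40 females, 4 groups)."""
    ds, truth = simulate_population(small_config(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    ds, _ = small_sim
    return analysis_cohort(ds)


@pytest.fixture(scope="session")
def small_dsi(small_sim, small_cohort):
    ds, _ = small_sim
    return compute_dsi(ds, small_cohort)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulated population (216 females, 13 groups)."""
    ds, truth = simulate_population(SimulationConfig(seed=1))
    return ds, truth


@pytest.fixture(scope="session")
def default_cohort(default_sim):
    ds, _ = default_sim
    return analysis_cohort(ds)


@pytest.fixture(scope="session")
def default_dsi(default_sim, default_cohort):
    ds, _ = default_sim
    return compute_dsi(ds, default_cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
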