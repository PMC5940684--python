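import numpy as np
import pytest

from twingrowth.cohort import simulate_cohort
from twingrowth.config import CohortConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort (8 MZ + 42 DZ pairs)."""
    cfg = CohortConfig(n_mz=8, n_dz=42, seed=11)
    measurements, covariates, truth = simulate_cohort(cfg)
    return cfg, measurements, covariates, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized cohort: 15 MZ + 133 DZ pairs."""
    cfg = CohortConfig(seed=5)
    measurements, covariates, truth = simulate_cohort(cfg)
    return cfg, measurements, covariates, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
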