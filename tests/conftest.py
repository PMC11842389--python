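import warnings

import numpy as np
import pytest

from safwre import CohortTable, SynthConfig, generate_cohort
from safwre.optimizers import SearchSpace

# xgboost emits benign device warnings on CPU-only hosts
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def table8_cohort() -> CohortTable:
    return generate_cohort(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def mechanism_cohort() -> CohortTable:
    return generate_cohort(SynthConfig(mode="mechanism", seed=11))


@pytest.fixture(scope="session")
def small_cohort() -> CohortTable:
    """A reduced cohort for fast model fits."""
    return generate_cohort(SynthConfig(n_impaired=80, n_normal=120, seed=3))


@pytest.fixture
def sphere_space() -> SearchSpace:
    return SearchSpace(np.full(2, -5.0), np.full(2, 5.0))


def sphere(x: np.ndarray) -> float:
    return float(np.sum(x**2))
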