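import numpy as np
import pytest

from driftchoice import CohortConfig, DDMParams
from driftchoice.cohort import generate_choice_menu


@pytest.fixture(scope="session")
def menu():
    return generate_choice_menu()


@pytest.fixture
def small_config():
    """Cohort sized for fast end-to-end tests (not the study-scale defaults)."""
    return CohortConfig(n_per_group=8, n_trials=40, n_addiction=40, n_titration=60, seed=11)


@pytest.fixture
def typical_params():
    return DDMParams(z=0.5, a=1.5, t0=0.3, dc=0.1, wm=0.05, wd=-0.01)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
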