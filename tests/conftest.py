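import numpy as np
import pytest

from gruntline import StudyDesign, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(n_piglets=12)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """One small study shared across read-only tests."""
    return simulate_study(small_design, seed=1)
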