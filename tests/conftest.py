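import numpy as np
import pytest

from drowsekit import SimProfile, simulate_cohort
from drowsekit.pipeline import extract_cohort_features

#: fixed cohort seed used across the suite (chosen once, not tuned)
COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_cohort():
    """Six simulated one-hour sessions at the default calibrated profile."""
    return simulate_cohort(SimProfile(), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_windows(default_cohort):
    """Window feature table of the default cohort (360 windows, 94 excluded)."""
    return extract_cohort_features(default_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
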