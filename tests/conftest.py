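import numpy as np
import pytest

from eegfuse.features import FuzzyEnConfig, Segment
from eegfuse.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort: 2 subjects x 6 trials of 12-s signal (2 segments each)."""
    return generate_cohort(SimConfig(n_subjects=2, n_trials=6, trial_seconds=12.0, seed=7))


@pytest.fixture
def random_segment(rng):
    sig = rng.standard_normal((32, 768)).astype(np.float32)
    return Segment(signal=sig, fs=128.0, window_seconds=6.0, subject=0, trial=0, window_index=0)


@pytest.fixture(scope="session")
def fuzzy_cfg():
    return FuzzyEnConfig()
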