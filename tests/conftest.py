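import numpy as np
import pytest

from eegdann.synthetic import SynthSpec, generate


@pytest.fixture(scope="session")
def small_multisubject():
    """Compact 3-subject set used by training-mechanics tests."""
    spec = SynthSpec(n_subjects=3, n_trials_per_session=6,
                     n_segments_per_trial=10, n_channels=8, n_bands=4,
                     n_classes=2, seed=11)
    fs, truth = generate(spec)
    return fs, truth, spec


@pytest.fixture(scope="session")
def seed_shaped():
    """A set with SEED-like metadata shape: 15 trials, several subjects."""
    spec = SynthSpec(n_subjects=4, n_sessions=2, n_trials_per_session=15,
                     n_segments_per_trial=4, n_channels=6, n_bands=5,
                     n_classes=3, seed=7)
    fs, _ = generate(spec)
    return fs


def rng(seed=0):
    return np.random.default_rng(seed)
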