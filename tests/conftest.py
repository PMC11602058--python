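import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import semgrasp as sg

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 500.0


@pytest.fixture(scope="session")
def two_tone():
    """2000-sample mixture of 50 Hz and 150 Hz unit sinusoids at 500 Hz."""
    t = np.arange(2000) / FS
    sig = np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 150 * t)
    return t, sig


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny synthetic dataset: 6 classes x 3 trials, defaults otherwise."""
    return sg.generate_dataset(sg.SynthConfig(trials_per_class=3, seed=11))


@pytest.fixture(scope="session")
def small_feature_table(small_dataset):
    """Feature table from the tiny dataset with K=4 and a coarse window hop."""
    recordings, _ = small_dataset
    windows = sg.segment_all(recordings, size=2000, step=500)
    X, y, names, groups = sg.compute_feature_table(windows, sg.VmdConfig(K=4))
    return X, y, names, groups
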