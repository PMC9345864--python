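import numpy as np
import pytest

from posturekit import FeatureTargets, make_posture


@pytest.fixture
def rng():
    return np.random.default_rng(20220802)


@pytest.fixture
def erect_session():
    """Noise-free perfectly erect stance, a few frames per window."""
    return make_posture(FeatureTargets(), noise_sd=0.0, seed=0, frames_per_window=3)


@pytest.fixture
def bent_session():
    """Noise-free session realizing a non-trivial target posture."""
    targets = FeatureTargets(f1=5.0, f2=2.0, f3=30.0, f4=20.0, f5=10.0, f7=25.0)
    return make_posture(targets, noise_sd=0.0, seed=0, frames_per_window=3)
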