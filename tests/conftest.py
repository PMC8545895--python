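import numpy as np
import pytest

from emgrasp import RunConfig
from emgrasp.synth import SynthSpec, default_synergy, generate_dataset


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def profile6():
    return default_synergy(6)


@pytest.fixture(scope="session")
def small_spec():
    # 2 reps x 6 grasps x 2 weights = 24 short trials: enough structure for
    # IO/preprocess/evaluate unit tests while staying fast
    return SynthSpec(n_channels=6, n_reps=2, trial_duration_s=2.0, seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
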