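import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from eeglrtc.synth import SyntheticSpec, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_trials_per_condition=8, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """8 task + 8 rest trials; shared across tests that only read it."""
    return gen_dataset(small_spec)
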