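import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles.py importable

import lesionseg as ls


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reduced_config():
    """Quarter-width config used for CPU-scale model tests."""
    return ls.ModelConfig.reduced(0.25, 96)


@pytest.fixture(scope="session")
def tiny_samples():
    """Eight deterministic synthetic samples at 96x96."""
    from lesionseg.synthetic_data import generate_dataset

    samples, _, _ = generate_dataset(8, size=96, seed=0)
    return samples
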