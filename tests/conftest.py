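import numpy as np
import pytest

from hypersmurf.simdata import SimConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """30 positives vs 300 negatives, learnable signal, bands included."""
    return simulate(SimConfig(n_pos=30, n_neg=300, d=6, separation=3.0, seed=11))
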