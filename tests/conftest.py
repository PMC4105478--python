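import sys
from pathlib import Path

import numpy as np
import pytest

# make the oracle module importable as `primal_pls` regardless of rootdir
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_toy(rng):
    """Small linearly separable two-class problem (n=12, p=8)."""
    n_half, p = 6, 8
    X = rng.normal(size=(2 * n_half, p))
    X[:n_half, 0] += 3.0
    labels = np.array(["pos"] * n_half + ["neg"] * n_half)
    return X, labels


@pytest.fixture
def three_class_toy(rng):
    n_per, p = 5, 10
    X = rng.normal(size=(3 * n_per, p))
    X[:n_per, 0] += 3.0
    X[n_per : 2 * n_per, 1] += 3.0
    labels = np.repeat(["a", "b", "c"], n_per)
    return X, labels
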