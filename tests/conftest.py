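import numpy as np
import pytest

from distillsurv import build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_survival_data(seed, n=50, p=4, censor_frac=0.3, ties=False):
    """Small ad-hoc right-censored dataset (not model-based; for oracles)."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(size=n) + 0.05
    if ties:
        t = np.round(t, 1) + 0.05
    event = (rng.random(n) > censor_frac).astype(int)
    event[rng.integers(0, n)] = 1  # guarantee at least one event
    X = rng.standard_normal((n, p))
    return build_dataset(t, event, X)


@pytest.fixture
def small_data():
    return random_survival_data(7, n=40, p=3)
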