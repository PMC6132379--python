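import numpy as np
import pytest

from robsel import LossSpec, SimConfig, make_dataset

LOSSES = [
    LossSpec("lad"),
    LossSpec("quantile", alpha=0.3),
    LossSpec("huber", c=1.345),
    LossSpec("lq", q=1.5),
    LossSpec("ols"),
]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_dataset():
    """A well-conditioned n=60, p=5 LAD-friendly dataset with 2 signals."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((60, 5))
    beta0 = np.array([1.5, -2.0, 0.0, 0.0, 0.0])
    y = X @ beta0 + rng.standard_normal(60)
    return X, y, beta0


def random_p2_instance(rng, n=20):
    """Small random two-covariate instance with coefficients inside the
    brute-force search box."""
    X = rng.standard_normal((n, 2))
    beta = rng.uniform(-2.0, 2.0, size=2)
    y = X @ beta + 0.3 * rng.standard_normal(n)
    return X, y, beta
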