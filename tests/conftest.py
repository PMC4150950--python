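import numpy as np
import pytest

from peplife import hl10_spec, simulate_dataset


@pytest.fixture(scope="session")
def hl10_like():
    """A default synthetic 10mer dataset (exponential link, n=189)."""
    ds, truth = simulate_dataset(hl10_spec(seed=11))
    return ds, truth


@pytest.fixture(scope="session")
def linear_10mer():
    """A 10mer dataset whose half-life is linear in the 8 planted dipeptides."""
    ds, truth = simulate_dataset(hl10_spec(seed=11, link="identity", intercept=0.5))
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)
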