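import numpy as np
import pytest

from sisquoc import BivariateTable, MarginVector


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_margin(rng, k: int) -> MarginVector:
    """A strictly positive random margin vector of length k."""
    return MarginVector(rng.dirichlet(np.ones(k)))


def random_2x2_table(rng) -> BivariateTable:
    """A valid random 2x2 probability table (uniform over the simplex)."""
    return BivariateTable(rng.dirichlet(np.ones(4)).reshape(2, 2))


class CountingRng:
    """Wraps a Generator and counts uniform() draws (sampler instrumentation)."""

    def __init__(self, rng):
        self._rng = rng
        self.uniform_calls = 0

    def uniform(self, *args, **kwargs):
        self.uniform_calls += 1
        return self._rng.uniform(*args, **kwargs)

    def __getattr__(self, name):
        return getattr(self._rng, name)
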