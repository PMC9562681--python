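import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from topotag import persistence
from topotag.synthetic import generate_slide


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Pay the one-off JIT compilation before any timed assertions."""
    persistence.warm_up()


@pytest.fixture(scope="session")
def small_slide():
    """A 60-spot slide with default gene models, shared across tests."""
    return generate_slide(n_spots=60, rng_seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
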