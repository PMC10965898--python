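import numpy as np
import pytest

from redescend import RegressionData, load_fixture


@pytest.fixture(scope="session")
def telephone():
    return load_fixture("telephone").data


@pytest.fixture(scope="session")
def china():
    return load_fixture("china").data


@pytest.fixture()
def clean_line():
    """Noise-free data exactly on y = 3 + 2x."""
    x = np.arange(10, dtype=float)
    return RegressionData(x, 3.0 + 2.0 * x, label="exact")


@pytest.fixture()
def seeded_sample():
    """A clean seeded draw from y = 2 + x + e with x ~ N(20, 10), n = 50."""
    rng = np.random.default_rng(7)
    x = rng.normal(20, 10, 50)
    y = 2.0 + x + rng.normal(0, 1, 50)
    return RegressionData(x, y, label="seeded-clean")
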