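import numpy as np
import pytest

from hospdea.dea import DMUSet
from hospdea.panel import load_fixture_panel


@pytest.fixture(scope="session")
def fixture_panel():
    return load_fixture_panel()


@pytest.fixture()
def toy_dmus():
    """Three DMUs with one input and one output, solvable by hand.

    A=(2,1), B=(4,4), C=(6,5). Under constant returns the output/input
    ratios are 0.5, 1.0 and 5/6, so theta_A = 0.5, theta_B = 1 and
    theta_C = 5/6. Under variable returns all three are hull vertices and
    score 1.
    """
    return DMUSet(
        inputs=np.array([[2.0, 4.0, 6.0]]),
        outputs=np.array([[1.0, 4.0, 5.0]]),
        labels=["A", "B", "C"],
    )


def random_dmus(rng, n=None, m=None, s=None):
    """A random small DMU set with strictly positive data."""
    n = n or int(rng.integers(2, 8))
    m = m or int(rng.integers(1, 4))
    s = s or int(rng.integers(1, 4))
    X = rng.uniform(0.5, 10.0, size=(m, n))
    Y = rng.uniform(0.5, 10.0, size=(s, n))
    return DMUSet(inputs=X, outputs=Y, labels=[f"D{i}" for i in range(n)])
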