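import numpy as np
import pytest

from keq import BivariateScoreTable, DiscreteScoreDistribution


@pytest.fixture
def toy3():
    """Symmetric three-point distribution on 0, 1, 2."""
    return DiscreteScoreDistribution(np.arange(3), [0.25, 0.5, 0.25])


@pytest.fixture
def toy5():
    """Asymmetric five-point distribution with counts (n = 100)."""
    counts = np.array([10.0, 25.0, 35.0, 20.0, 10.0])
    return DiscreteScoreDistribution.from_counts(np.arange(5), counts)


@pytest.fixture
def random_dist():
    """A moderately irregular 21-point distribution with counts."""
    rng = np.random.default_rng(1234)
    counts = rng.integers(1, 60, size=21).astype(float)
    return DiscreteScoreDistribution.from_counts(np.arange(21), counts)


@pytest.fixture
def biv_table():
    """A 4x3 bivariate table with positive dependence and raw counts."""
    rng = np.random.default_rng(7)
    x = np.arange(4)
    a = np.arange(3)
    logits = 0.3 * np.outer(x - 1.5, a - 1.0) - 0.1 * (x[:, None] - 1.5) ** 2
    p = np.exp(logits)
    p /= p.sum()
    counts = rng.multinomial(500, p.ravel()).reshape(p.shape).astype(float)
    return BivariateScoreTable.from_counts(x, a, counts)
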