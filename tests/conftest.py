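import numpy as np
import pytest

from npbf.datasets import illustrative_outcomes, shoulder_pain
from npbf.ranks import TwoSampleData


@pytest.fixture(scope="session")
def outcomes17() -> TwoSampleData:
    """17-value metric dataset, oriented so theta_hat = 0.8."""
    return illustrative_outcomes()


@pytest.fixture(scope="session")
def pain() -> TwoSampleData:
    """Shoulder-tip-pain ordinal data, treatment (suction) as first sample."""
    return shoulder_pain()


def pairwise_theta(x1, x2) -> float:
    """Brute-force Mann-Whitney effect: strict wins plus half of the ties
    over all n1*n2 cross pairs."""
    x1 = np.asarray(x1, float)[:, None]
    x2 = np.asarray(x2, float)[None, :]
    return float(np.mean((x1 < x2) + 0.5 * (x1 == x2)))


def pairwise_tie_fraction(x1, x2) -> float:
    """Brute-force proportion of tied cross pairs."""
    x1 = np.asarray(x1, float)[:, None]
    x2 = np.asarray(x2, float)[None, :]
    return float(np.mean(x1 == x2))


def random_tied_samples(rng, max_n=8, n_values=5):
    """Small pair of samples drawn from a coarse grid so ties are common."""
    n1 = int(rng.integers(2, max_n + 1))
    n2 = int(rng.integers(2, max_n + 1))
    x1 = rng.integers(0, n_values, size=n1).astype(float)
    x2 = rng.integers(0, n_values, size=n2).astype(float)
    return x1, x2
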