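import numpy as np
import pytest

from connectoclass import CohortConfig, generate_cohort, preprocess_cohort


def symmetric_from_upper(n, values):
    """Build a zero-diagonal symmetric matrix from upper-triangle values."""
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = values
    return m + m.T


@pytest.fixture(scope="session")
def small_cohort():
    """One default-condition cohort (18 CTL / 14 MDD, 68 nodes), preprocessed."""
    cohort = generate_cohort(CohortConfig(seed=11))
    graphs = preprocess_cohort(cohort.matrices)
    return cohort, graphs


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_adjacency(n, p, rng):
    """Random simple undirected 0/1 adjacency matrix."""
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a + a.T
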