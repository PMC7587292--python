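import numpy as np
import pytest

from eemap.affinities import AffinityPair, build_affinity_pair
from eemap.containers import ExpressionMatrix
from eemap.synthetic import generate_gaussian_clusters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """8 cells x 5 genes of positive expression-like values."""
    return ExpressionMatrix(rng.gamma(2.0, 1.0, size=(8, 5)))


def random_affinity_pair(rng, n, lam=1.0):
    """A valid random AffinityPair for objective/gradient tests."""
    wp = rng.uniform(0.1, 1.0, (n, n))
    wp = 0.5 * (wp + wp.T)
    np.fill_diagonal(wp, 0.0)
    wm = rng.uniform(0.1, 1.0, (n, n))
    wm = 0.5 * (wm + wm.T)
    np.fill_diagonal(wm, 0.0)
    return AffinityPair(wp, wm, lam)


@pytest.fixture
def two_clusters():
    """Two well-separated Gaussian blobs in 10-D (60 cells)."""
    m, labels = generate_gaussian_clusters(
        n_clusters=2, n_per_cluster=30, dim=10, separation=40.0, seed=7
    )
    return m, labels


@pytest.fixture
def cluster_affinities(two_clusters):
    m, _ = two_clusters
    return build_affinity_pair(m, mode="entropic", parameter=10.0, lam=1.0)
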