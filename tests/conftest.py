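import numpy as np
import pytest

from msdelm.elm import FeatureTable
from msdelm.synthetic import ClusterSpec, gen_clusters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table(rng):
    """Tiny well-separated 3-class table for fast classifier tests."""
    return gen_clusters(ClusterSpec(n_classes=3, samples_per_class=30, df=5,
                                    separation=6.0, seed=7))


@pytest.fixture
def tiny_table():
    """Fixed 6-sample, 2-feature, 2-class table for exact-value tests."""
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0],
                  [5.0, 5.0], [6.0, 5.0], [5.0, 6.0]])
    y = np.array([1, 1, 1, 2, 2, 2])
    return FeatureTable(X, y)
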