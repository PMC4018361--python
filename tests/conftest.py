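import numpy as np
import pytest

from ldapls import LabeledDataset


def random_two_class(rng, n=40, k=4, sep=2.0):
    """A generic separable-ish two-class dataset for property tests."""
    half = n // 2
    X = rng.standard_normal((2 * half, k))
    shift = rng.standard_normal(k)
    shift = sep * shift / np.linalg.norm(shift)
    y = np.r_[np.full(half, -1), np.full(half, 1)]
    X[y == 1] += shift
    return X, y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def eight_point_dataset():
    """Two isotropic 4-point classes with known means and scatter.

    Class -1: (1,0),(3,0),(2,1),(2,-1) around m1=(2,0);
    class +1 the same cross shifted to m2=(7,0).
    S_W = 4*I, S_B = [[25,0],[0,0]].
    """
    X = np.array(
        [
            [1.0, 0.0], [3.0, 0.0], [2.0, 1.0], [2.0, -1.0],
            [6.0, 0.0], [8.0, 0.0], [7.0, 1.0], [7.0, -1.0],
        ]
    )
    y = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
    return LabeledDataset(X=X, y=y)


@pytest.fixture
def dataset_factory(rng):
    def make(n=40, k=4, sep=2.0):
        return random_two_class(rng, n=n, k=k, sep=sep)

    return make
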