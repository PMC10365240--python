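import numpy as np
import pytest

from smfcnet import normalize_series


class EdgeProbeClassifier:
    """Fast deterministic stand-in classifier for structural tests.

    Thresholds the branch-mean value of a single connectivity entry at the
    midpoint of the class means. Its accuracy collapses when that entry (or
    either of its regions) is occluded, which makes ensemble bookkeeping and
    occlusion attribution testable in milliseconds.
    """

    def __init__(self, edge=(0, 1), seed=0):
        self.edge = edge
        self.seed = seed

    def fit(self, X, y):
        i, j = self.edge
        feat = np.asarray(X)[:, :, i, j].mean(axis=1)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        mu0 = feat[y == self.classes_[0]].mean()
        mu1 = feat[y == self.classes_[1]].mean()
        self.threshold_ = (mu0 + mu1) / 2.0
        self.sign_ = 1.0 if mu1 >= mu0 else -1.0
        return self

    def _score(self, X):
        i, j = self.edge
        feat = np.asarray(X)[:, :, i, j].mean(axis=1)
        return self.sign_ * (feat - self.threshold_)

    def predict_proba(self, X):
        p1 = 1.0 / (1.0 + np.exp(-5.0 * self._score(X)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self._score(X) > 0).astype(int)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def random_ts(rng):
    """A normalized 30 x 6 random subject."""
    return normalize_series(rng.standard_normal((30, 6)))


@pytest.fixture
def probe_factory():
    def make(seed=0, edge=(0, 1), **_):
        return EdgeProbeClassifier(edge=edge, seed=seed)
    return make


def make_probe_dataset(rng, n=40, d=3, n_rois=6, edge=(0, 1), shift=2.0):
    """Stacks in which only ``edge`` separates the classes."""
    X = rng.standard_normal((n, d, n_rois, n_rois)) * 0.05
    X = (X + X.transpose(0, 1, 3, 2)) / 2
    y = np.arange(n) % 2
    i, j = edge
    X[y == 1, :, i, j] += shift
    X[y == 1, :, j, i] += shift
    return X, y
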