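import numpy as np
import pytest

from neurogeom import synthdata
from neurogeom.gkr import fit_gkr


@pytest.fixture(scope="session")
def ring_spec():
    return synthdata.build_tuning_model("ring1d", n_neurons=10, seed=1)


@pytest.fixture(scope="session")
def ring_data(ring_spec):
    return synthdata.sample_dataset(ring_spec, n_points=300, seed=3)


@pytest.fixture(scope="session")
def ring_gkr(ring_data):
    """One fitted GKR model on the standard ring fixture, shared widely."""
    return fit_gkr(ring_data, seed=0)


def make_torus_cloud(n=1000, seed=0, noise=0.05):
    """Flat-torus embedding in R^4 with small additive noise."""
    rng = np.random.default_rng(seed)
    th = rng.uniform(0, 2 * np.pi, n)
    ph = rng.uniform(0, 2 * np.pi, n)
    X = np.stack([np.cos(th), np.sin(th), np.cos(ph), np.sin(ph)], axis=1)
    return X + noise * rng.standard_normal(X.shape)


@pytest.fixture(scope="session")
def torus_cloud():
    return make_torus_cloud


class AnalyticModel:
    """Deterministic mean/covariance functions as a model stand-in."""

    def __init__(self, mean_fn, cov_fn):
        self._mean = mean_fn
        self._cov = cov_fn

    def predict_mean(self, X):
        X = np.atleast_2d(X)
        return np.stack([self._mean(x) for x in X])

    def predict_cov(self, X):
        X = np.atleast_2d(X)
        return np.stack([self._cov(x) for x in X])

    def predict(self, X):
        return self.predict_mean(X), self.predict_cov(X)


@pytest.fixture(scope="session")
def analytic_model_cls():
    return AnalyticModel
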