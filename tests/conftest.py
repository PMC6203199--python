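"""Shared fixtures and the dense-algebra scoring oracle.

The oracle evaluates the score formulas directly — explicit rank-k
pseudo-inverse, explicit quadratic forms — independent of the whitening
route used by the implementation.
"""

import numpy as np
import pytest

from pines.scoring import estimate_background_model
from pines.simulate import generate_fixture_tracks


class DenseOracle:
    """Brute-force evaluation of the quadratic forms via an explicit Σ̂⁺."""

    def __init__(self, X: np.ndarray, k: int):
        self.mu = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        keep = min(k, int(np.sum(evals > 1e-10 * evals[0])))
        self.pinv = sum(
            (1.0 / evals[i]) * np.outer(evecs[:, i], evecs[:, i]) for i in range(keep)
        )

    def quad(self, a, b, w):
        W = np.diag(w)
        return float((a - self.mu) @ W @ self.pinv @ W @ (b - self.mu))

    def mahalanobis(self, x, w):
        return np.sqrt(self.quad(x, x, w))

    def cosine(self, x, w):
        ones = np.ones_like(x)
        return self.quad(x, ones, w) / (self.mahalanobis(x, w) * self.mahalanobis(ones, w))

    def score(self, x, w):
        ones = np.ones_like(x)
        cos = np.clip(self.cosine(x, w), -1.0, 1.0)
        return np.arccos(cos) / (self.mahalanobis(x, w) * self.mahalanobis(ones, w))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def random_instance(rng):
    """A random background matrix, fitted model, oracle and probe vectors."""

    def make(n=150, d=12, k=None, p=0.35, seed=None):
        local = np.random.default_rng(seed) if seed is not None else rng
        k = k if k is not None else d
        X = (local.random((n, d)) < p).astype(float)
        while np.any(X.std(axis=0) == 0):  # avoid constant columns at tiny n
            X = (local.random((n, d)) < p).astype(float)
        model = estimate_background_model(X, k=k)
        oracle = DenseOracle(X, k=k)
        return X, model, oracle

    return make


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    return generate_fixture_tracks(tmp_path_factory.mktemp("bundle"), seed=7)
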