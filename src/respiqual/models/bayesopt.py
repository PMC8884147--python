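"""Minimal Gaussian-process Bayesian optimization (expected improvement).

Used to tune the SVM's box constraint and kernel scale by minimizing
cross-validated classification error over a log-uniform box.  A Matern-5/2
GP is fit to the evaluations so far; the next point maximizes expected
improvement over a random candidate set.  Everything is seeded and
deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel


def bayes_minimize(
    objective,
    n_dims: int,
    n_calls: int = 25,
    n_initial: int = 8,
    seed: int = 0,
    n_candidates: int = 512,
):
    """Minimize ``objective`` over the unit cube ``[0, 1]^n_dims``.

    Returns ``(x_best, y_best, X, y)``.  The caller maps unit coordinates to
    its parameter space (e.g. log-uniform).
    """
    rng = np.random.default_rng(seed)
    X = list(rng.uniform(size=(min(n_initial, n_calls), n_dims)))
    y = [float(objective(x)) for x in X]

    kernel = ConstantKernel(1.0) * Matern(length_scale=0.3, nu=2.5) + WhiteKernel(1e-4)
    while len(y) < n_calls:
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31 - 1))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP convergence chatter on flat objectives
            gp.fit(np.array(X), np.array(y))
        cand = rng.uniform(size=(n_candidates, n_dims))
        mu, sigma = gp.predict(cand, return_std=True)
        best = min(y)
        sigma = np.maximum(sigma, 1e-12)
        z = (best - mu) / sigma
        ei = (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)
        x_next = cand[int(np.argmax(ei))]
        X.append(x_next)
        y.append(float(objective(x_next)))

    i_best = int(np.argmin(y))
    return X[i_best], y[i_best], np.array(X), np.array(y)


def unit_to_loguniform(u: np.ndarray, low: float, high: float) -> np.ndarray:
    """Map unit-cube coordinates to a log-uniform range."""
    lo, hi = np.log10(low), np.log10(high)
    return 10.0 ** (lo + np.asarray(u) * (hi - lo))
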