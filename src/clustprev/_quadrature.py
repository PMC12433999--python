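"""Shared one-dimensional Gaussian quadrature helpers."""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import expit, roots_hermitenorm


@lru_cache(maxsize=32)
def hermite_nodes(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss-Hermite nodes and normalised weights.

    Returns ``(z, w)`` with ``sum(w) == 1`` so that ``sum(w * f(z))``
    approximates ``E[f(Z)]`` for ``Z ~ N(0, 1)``.
    """
    z, w = roots_hermitenorm(n_points)
    return z, w / np.sqrt(2.0 * np.pi)


def mean_expit_gaussian(mu: float | np.ndarray, sigma2: float, n_points: int = 201) -> float | np.ndarray:
    """E[logit^{-1}(mu + Z)] for Z ~ N(0, sigma2), by Gauss-Hermite quadrature.

    This is the population-averaged success probability of a logistic model
    with a Gaussian random intercept of variance ``sigma2``.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if sigma2 == 0:
        return expit(mu)
    z, w = hermite_nodes(n_points)
    mu_arr = np.asarray(mu, dtype=float)
    vals = expit(mu_arr[..., None] + np.sqrt(sigma2) * z) @ w
    return float(vals) if np.ndim(mu) == 0 else vals
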