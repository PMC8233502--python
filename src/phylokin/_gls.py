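"""Shared generalized-least-squares linear algebra.

Everything works through a Cholesky factorization of the tip covariance;
a tiny ridge (relative to the mean diagonal) is added once if the matrix
is numerically singular, with a logged warning.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

RIDGE = 1e-10


def chol(V: np.ndarray):
    """Cholesky factor of V (ridge fallback).  Returns (factor, logdet)."""
    V = np.asarray(V, dtype=float)
    try:
        c = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        logger.warning("covariance numerically singular; adding ridge %g", RIDGE)
        c = cho_factor(V + RIDGE * np.mean(np.diag(V)) * np.eye(len(V)),
                       lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    return c, logdet


def solve(c, B: np.ndarray) -> np.ndarray:
    return cho_solve(c, B)


def gls_mean(y: np.ndarray, c) -> float:
    """Intercept-only GLS estimate (the phylogenetic mean)."""
    one = np.ones_like(y)
    iV1 = solve(c, one)
    return float(one @ solve(c, y) / (one @ iV1))


def profile_loglik(y: np.ndarray, V: np.ndarray):
    """Profiled MVN log-likelihood of y ~ N(mu 1, sigma2 V).

    mu and sigma2 are profiled out analytically:
    ``l = -1/2 [n ln(2 pi sigma2) + ln|V| + n]`` with
    ``sigma2 = e' V^-1 e / n``.  Returns (loglik, mu, sigma2).
    """
    n = len(y)
    c, logdet = chol(V)
    mu = gls_mean(y, c)
    e = y - mu
    sigma2 = float(e @ solve(c, e)) / n
    sigma2 = max(sigma2, 1e-300)
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, mu, sigma2
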