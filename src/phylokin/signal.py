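"""Phylogenetic-signal detection.

Five detectors are implemented as scikit-learn style estimators, each
consuming a trait vector plus one tip-by-tip matrix from `tree_ops`:

* :class:`PagelLambda` — ML estimate of the branch-length multiplier
  lambda under a Brownian-motion (BM) model, with a likelihood-ratio test
  against lambda = 0 (no signal).
* :class:`BlombergK` — the K and K* variance-ratio statistics calibrated
  so K = 1 under pure BM, with a tip-shuffling permutation test.
* :class:`MoranI` — spatial autocorrelation with reciprocal patristic
  distance weights.
* :class:`AbouheifCmean` — the same autocorrelation form with the
  topology-only Abouheif proximity.

A trait is called "signal present" when at least three of the five
detectors are significant at 0.05 (:func:`signal_panel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

from . import tree_ops
from ._gls import chol, gls_mean, profile_loglik, solve
from .trait_data import TraitTable

METHODS = ("lambda", "K", "Kstar", "moran_I", "cmean")


class DegenerateTraitError(ValueError):
    """The trait vector is constant; signal statistics are undefined."""


def _check_vector(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise DegenerateTraitError("constant trait vector")
    return y


def alpha_bin(p: float) -> str:
    """Bin a p-value into the conventional alpha levels.

    Boundary values fall into the weaker bin (p = 0.05 exactly -> "ns").
    """
    if not 0 < p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    for level in (0.001, 0.01, 0.05):
        if p < level:
            return str(level)
    return "ns"


# ---------------------------------------------------------------------------
# Pagel's lambda


class PagelLambda(BaseEstimator):
    """ML fit of Pagel's lambda under Brownian motion.

    The profiled log-likelihood
    ``l(lam) = -1/2 [n ln(2 pi sigma2) + ln|C(lam)| + n]`` is maximized
    over ``lam in [0, lambda_max]``, where ``C(lam)`` multiplies the
    off-diagonal covariance by ``lam`` and ``lambda_max`` is the largest
    value keeping the matrix valid (slightly above 1 for ultrametric
    trees).  The search is a coarse grid followed by bounded refinement
    around the best grid point, which also covers the multi-start role.

    Parameters
    ----------
    chisq_mode : {"mixture", "chi2"}
        Null reference for the likelihood-ratio test of lambda = 0.  The
        default 50:50 chi2_0/chi2_1 mixture is the correct reference for a
        parameter on its boundary; plain chi2_1 is conservative.
    grid_size : int
        Coarse-grid resolution of the first search stage.
    tol : float
        Absolute tolerance of the bounded refinement.
    """

    def __init__(self, chisq_mode: str = "mixture", grid_size: int = 25,
                 tol: float = 1e-6):
        self.chisq_mode = chisq_mode
        self.grid_size = grid_size
        self.tol = tol

    def fit(self, C, y):
        y = _check_vector(y)
        A = np.asarray(C, dtype=float)
        if len(y) != len(A):
            raise ValueError("trait vector and covariance dimension mismatch")
        if len(y) < 3:
            raise ValueError("need at least 3 tips")
        lmax = tree_ops.lambda_max(A)
        D = np.diag(np.diag(A))
        off = A - D

        def loglik(lam):
            return profile_loglik(y, lam * off + D)[0]

        # C(lambda_max) is singular by construction; search just inside it
        grid = np.linspace(0.0, lmax * (1.0 - 1e-6), self.grid_size)
        ll_grid = np.array([loglik(l) for l in grid])
        k = int(np.argmax(ll_grid))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        if hi > lo:
            res = minimize_scalar(lambda l: -loglik(l), bounds=(lo, hi),
                                  method="bounded",
                                  options={"xatol": self.tol})
            lam_hat, ll_hat = float(res.x), -float(res.fun)
        else:
            lam_hat, ll_hat = float(grid[k]), float(ll_grid[k])
        if ll_grid[k] > ll_hat:  # refinement never beats the grid? keep best
            lam_hat, ll_hat = float(grid[k]), float(ll_grid[k])

        ll0 = float(ll_grid[0])
        lrt = max(2.0 * (ll_hat - ll0), 0.0)
        if self.chisq_mode == "mixture":
            p = 1.0 if lrt == 0.0 else min(1.0, 0.5 * stats.chi2.sf(lrt, df=1))
        elif self.chisq_mode == "chi2":
            p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
        else:
            raise ValueError(f"unknown chisq_mode {self.chisq_mode!r}")

        _, mu, sigma2 = profile_loglik(y, lam_hat * off + D)
        self.lambda_ = lam_hat
        self.lambda_max_ = lmax
        self.sigma2_ = sigma2
        self.mu_ = mu
        self.loglik_ = ll_hat
        self.loglik0_ = ll0
        self.lrt_ = lrt
        self.p_value_ = max(p, np.finfo(float).tiny)
        self.statistic_ = lam_hat
        return self


def fit_lambda_ml(y, C, chisq_mode: str = "mixture"):
    """Functional wrapper: returns (lambda, sigma2, mu, loglik, p)."""
    est = PagelLambda(chisq_mode=chisq_mode).fit(C, y)
    return est.lambda_, est.sigma2_, est.mu_, est.loglik_, est.p_value_


# ---------------------------------------------------------------------------
# Blomberg's K / K*


class BlombergK(BaseEstimator):
    """Blomberg's K and K* with a tip-shuffling permutation test.

    K compares the observed ratio of the "star" mean squared error about
    the phylogenetically (GLS) estimated mean to the BM-whitened mean
    squared error against its BM expectation
    ``[tr(C) - n / (1' C^-1 1)] / (n - 1)``; K* differs only in centering
    the numerator about the arithmetic mean.  Under pure BM, E[K] ~ 1.
    The permutation p-value counts shuffles whose whitened MSE is at most
    the observed one (small MSE = strong signal), observed included:
    ``p = (1 + #{MSE_perm <= MSE_obs}) / (n_perm + 1)``.
    """

    def __init__(self, n_perm: int = 999, seed: int = 0):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, C, y):
        y = _check_vector(y)
        A = np.asarray(C, dtype=float)
        n = len(y)
        if n < 4:
            raise ValueError("need at least 4 tips")
        c, _ = chol(A)
        one = np.ones(n)
        iC1 = solve(c, one)
        s1 = float(one @ iC1)
        w = iC1 / s1  # GLS-mean weights
        expected = (np.trace(A) - n / s1) / (n - 1)

        def mses(Y):
            # Y: (n, m) columns of trait vectors
            a = w @ Y
            E = Y - a
            mse = np.sum(E * solve(c, E), axis=0) / (n - 1)
            mse0 = np.sum(E * E, axis=0) / (n - 1)
            return mse, mse0

        mse, mse0 = mses(y[:, None])
        ybar = y.mean()
        mse0_star = float(np.sum((y - ybar) ** 2)) / (n - 1)
        K = float(mse0[0] / mse[0]) / expected
        Kstar = mse0_star / float(mse[0]) / expected

        rng = np.random.default_rng(self.seed)
        perms = rng.permuted(np.tile(y, (self.n_perm, 1)), axis=1).T
        mse_p, _ = mses(perms)
        p = (1 + int(np.sum(mse_p <= mse[0] + 1e-15))) / (self.n_perm + 1)

        self.statistic_ = K
        self.kstar_ = Kstar
        self.expected_ratio_ = float(expected)
        self.p_value_ = p
        return self


def blomberg_k(y, tree, n_perm: int = 999, seed: int = 0):
    """Functional wrapper over a tree: returns (K, Kstar, p)."""
    C = tree_ops.bm_covariance(tree)
    if isinstance(y, (dict, pd.Series)):
        y = pd.Series(y).reindex(list(C.index)).to_numpy()
    est = BlombergK(n_perm=n_perm, seed=seed).fit(C, np.asarray(y, float))
    return est.statistic_, est.kstar_, est.p_value_


# ---------------------------------------------------------------------------
# Autocorrelation statistics


class MoranI(BaseEstimator):
    """Moran's I with arbitrary proximity weights.

    ``I = (n / S0) * z' W z / z' z`` with ``z = y - ybar`` and
    ``S0 = sum(W)``.  The permutation null has mean -1/(n-1); the test is
    one-sided toward positive autocorrelation (signal).
    """

    statistic_name = "moran_I"

    def __init__(self, n_perm: int = 999, seed: int = 0):
        self.n_perm = n_perm
        self.seed = seed

    @staticmethod
    def _stat(Z: np.ndarray, W: np.ndarray, s0: float) -> np.ndarray:
        num = np.sum(Z * (W @ Z), axis=0)
        den = np.sum(Z * Z, axis=0)
        return (Z.shape[0] / s0) * num / den

    def fit(self, W, y):
        y = _check_vector(y)
        A = np.asarray(W, dtype=float)
        if np.any(np.diag(A) != 0) or np.any(A < 0):
            raise ValueError("weights must be non-negative with a zero diagonal")
        n = len(y)
        s0 = float(A.sum())
        z = y - y.mean()
        obs = float(self._stat(z[:, None], A, s0)[0])
        rng = np.random.default_rng(self.seed)
        perms = rng.permuted(np.tile(z, (self.n_perm, 1)), axis=1).T
        stat_p = self._stat(perms, A, s0)
        p = (1 + int(np.sum(stat_p >= obs - 1e-15))) / (self.n_perm + 1)
        self.statistic_ = obs
        self.expected_ = -1.0 / (n - 1)
        self.p_value_ = p
        return self


class AbouheifCmean(MoranI):
    """Moran-form autocorrelation with the Abouheif proximity matrix."""

    statistic_name = "cmean"


def morans_i(y, W, n_perm: int = 999, seed: int = 0):
    est = MoranI(n_perm=n_perm, seed=seed).fit(W, np.asarray(y, float))
    return est.statistic_, est.p_value_


def abouheif_cmean(y, A, n_perm: int = 999, seed: int = 0):
    est = AbouheifCmean(n_perm=n_perm, seed=seed).fit(A, np.asarray(y, float))
    return est.statistic_, est.p_value_


# ---------------------------------------------------------------------------
# Panels


@dataclass(frozen=True)
class SignalResult:
    method: str
    statistic: float
    p_value: float
    alpha: str
    settings: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SignalPanel:
    trait: str
    results: dict  # method -> SignalResult
    presence: bool
    n: int
    warning: str | None = None


@dataclass
class SignalConfig:
    n_perm: int = 999
    seed: int = 0
    row_normalize: bool = True
    chisq_mode: str = "mixture"


def _spawn_seeds(seed: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(k)]


def signal_panel(trait: str, table: TraitTable, tree,
                 config: SignalConfig | None = None) -> SignalPanel:
    """Run all five detectors on one trait; majority vote on presence.

    The trait vector is restricted to tips shared between table and tree
    (pairwise deletion), the tree pruned accordingly.  Presence is called
    when at least 3 of the 5 methods reach p < 0.05.
    """
    config = config or SignalConfig()
    yv = table.trait_vector(trait)
    shared = [l for l in tree_ops.tip_labels(tree) if l in yv.index]
    warning = None
    if len(shared) < 10:
        warning = f"only {len(shared)} shared tips"
    sub = tree_ops.prune_to(tree, shared)
    labels = tree_ops.tip_labels(sub)
    y = yv.loc[labels].to_numpy(dtype=float)

    C = tree_ops.bm_covariance(sub)
    W = tree_ops.moran_weights(tree_ops.patristic_matrix(sub),
                               row_normalize=config.row_normalize)
    A = tree_ops.abouheif_proximity(sub)
    s_k, s_i, s_c = _spawn_seeds(config.seed, 3)

    lam = PagelLambda(chisq_mode=config.chisq_mode).fit(C, y)
    kst = BlombergK(n_perm=config.n_perm, seed=s_k).fit(C, y)
    mor = MoranI(n_perm=config.n_perm, seed=s_i).fit(W, y)
    cme = AbouheifCmean(n_perm=config.n_perm, seed=s_c).fit(A, y)

    perm = {"n_perm": config.n_perm}
    results = {
        "lambda": SignalResult("lambda", lam.lambda_, lam.p_value_,
                               alpha_bin(lam.p_value_),
                               {"chisq_mode": config.chisq_mode}),
        "K": SignalResult("K", kst.statistic_, kst.p_value_,
                          alpha_bin(kst.p_value_), {**perm, "seed": s_k}),
        "Kstar": SignalResult("Kstar", kst.kstar_, kst.p_value_,
                              alpha_bin(kst.p_value_), {**perm, "seed": s_k}),
        "moran_I": SignalResult("moran_I", mor.statistic_, mor.p_value_,
                                alpha_bin(mor.p_value_),
                                {**perm, "seed": s_i,
                                 "row_normalize": config.row_normalize}),
        "cmean": SignalResult("cmean", cme.statistic_, cme.p_value_,
                              alpha_bin(cme.p_value_), {**perm, "seed": s_c}),
    }
    n_sig = sum(r.p_value < 0.05 for r in results.values())
    return SignalPanel(trait=trait, results=results, presence=n_sig >= 3,
                       n=len(labels), warning=warning)


def panel_frame(panels: list[SignalPanel]) -> pd.DataFrame:
    """Stack panels into a trait x (method statistic, alpha) table."""
    rows = []
    for p in panels:
        row = {"trait": p.trait, "n": p.n, "presence": p.presence}
        for m in METHODS:
            r = p.results[m]
            row[f"{m}_stat"] = r.statistic
            row[f"{m}_alpha"] = r.alpha
        rows.append(row)
    return pd.DataFrame(rows)
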