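"""Ordinary and phylogenetic generalized least squares on trait pairs.

PGLS fits ``y = X beta + e`` with ``e ~ N(0, sigma2 * C(lambda))``, where
``C`` is the Brownian-motion tip covariance and lambda rescales its
off-diagonal entries.  The default lambda policy for a trait pair is the
mean of the two per-trait ML estimates, capped at 1; with lambda = 0 (or
a star tree) the fit reduces to ordinary least squares.

Variance explained is reported as ``100 * R^2`` with the generalized
``R^2 = 1 - RSS/TSS`` computed in the whitened metric, so OLS and PGLS
percentages are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import tree_ops
from ._gls import chol, gls_mean, solve
from .signal import PagelLambda, alpha_bin
from .trait_data import TraitTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionFit:
    params: pd.Series          # intercept first
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    loglik: float
    r_squared: float
    lambda_used: float | None
    n: int

    @property
    def slope(self) -> float:
        return float(self.params.iloc[1])

    @property
    def slope_p(self) -> float:
        return float(self.pvalues.iloc[1])


class CollinearityError(ValueError):
    pass


def fit_gls(y, X, V=None, names=None, lambda_used=None) -> RegressionFit:
    """Generalized least squares with a known (up to scale) covariance.

    ``beta = (X' V^-1 X)^-1 X' V^-1 y``; coefficient tests are t with
    n - k degrees of freedom; ``V=None`` means the identity (OLS).
    ``R^2 = 1 - RSS/TSS`` with both sums in the V^-1 metric and TSS about
    the GLS intercept-only mean.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    n, k = X.shape
    if n < k + 1:
        raise ValueError("too few observations for the design")
    if names is None:
        names = ["const"] + [f"x{i}" for i in range(1, k)]

    if V is None:
        c = None
        iX, iy = X, y
    else:
        c, _ = chol(np.asarray(V, dtype=float))
        iX, iy = solve(c, X), solve(c, y)

    XtiX = X.T @ iX
    if np.linalg.matrix_rank(XtiX) < k:
        _, R = np.linalg.qr(iX)
        rdiag = np.abs(np.diag(R))
        bad = [names[j] for j in range(k)
               if rdiag[j] < 1e-10 * max(rdiag.max(), 1.0)]
        raise CollinearityError(f"rank-deficient design; collinear columns: {bad or names}")
    beta = np.linalg.solve(XtiX, X.T @ iy)
    resid = y - X @ beta
    iresid = resid if c is None else solve(c, resid)
    rss = float(resid @ iresid)

    mu = gls_mean(y, c) if c is not None else float(y.mean())
    dev = y - mu
    idev = dev if c is None else solve(c, dev)
    tss = float(dev @ idev)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    r2 = float(min(max(r2, 0.0), 1.0))

    sigma2 = rss / (n - k)
    cov = sigma2 * np.linalg.inv(XtiX)
    bse = np.sqrt(np.diag(cov))
    tval = beta / bse
    pval = 2.0 * stats.t.sf(np.abs(tval), df=n - k)
    logdet = 0.0 if c is None else 2.0 * np.sum(np.log(np.diag(c[0])))
    s2_ml = max(rss / n, 1e-300)
    loglik = -0.5 * (n * np.log(2 * np.pi * s2_ml) + logdet + n)
    return RegressionFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tval, index=names),
        pvalues=pd.Series(pval, index=names),
        loglik=float(loglik), r_squared=r2,
        lambda_used=lambda_used, n=n)


class PhylogeneticGLS(BaseEstimator):
    """scikit-learn estimator wrapper around :func:`fit_gls`.

    Parameters are the lambda policy; the tip covariance is passed to
    ``fit`` alongside the data (like a precomputed kernel).  With
    ``lam=0`` on an ultrametric tree the estimator is plain linear
    regression.

    Attributes (after fit): ``coef_``, ``intercept_``, ``r_squared_``,
    ``pvalues_``, ``result_`` (the full :class:`RegressionFit`).
    """

    def __init__(self, lam: float | None = 1.0, fit_intercept: bool = True):
        self.lam = lam
        self.fit_intercept = fit_intercept

    def fit(self, X, y, C=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(y)) != 1:
            X = X.T
        design = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        V = None
        if C is not None and self.lam is not None:
            V = tree_ops.lambda_transform(pd.DataFrame(np.asarray(C, float)),
                                          self.lam).to_numpy()
        self.result_ = fit_gls(y, design, V=V, lambda_used=self.lam)
        p = self.result_.params.to_numpy()
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(p[0]), p[1:]
        else:
            self.intercept_, self.coef_ = 0.0, p
        self.r_squared_ = self.result_.r_squared
        self.pvalues_ = self.result_.pvalues
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.coef_):
            X = X.T
        return self.intercept_ + X @ self.coef_


@dataclass(frozen=True)
class TraitPairResult:
    trait_x: str
    trait_y: str
    ols: RegressionFit
    pgls: RegressionFit
    lambda_pair: float
    subset: str = "all"

    @property
    def variance_explained_ols(self) -> float:
        return 100.0 * self.ols.r_squared

    @property
    def variance_explained_pgls(self) -> float:
        return 100.0 * self.pgls.r_squared

    @property
    def alpha_ols(self) -> str:
        return alpha_bin(self.ols.slope_p)

    @property
    def alpha_pgls(self) -> str:
        return alpha_bin(self.pgls.slope_p)


def _aligned_pair(trait_x, trait_y, table, tree):
    x = table.trait_vector(trait_x)
    y = table.trait_vector(trait_y)
    shared = [l for l in tree_ops.tip_labels(tree)
              if l in x.index and l in y.index]
    if len(shared) < 10:
        return None
    sub = tree_ops.prune_to(tree, shared)
    labels = tree_ops.tip_labels(sub)
    return (x.loc[labels].to_numpy(float), y.loc[labels].to_numpy(float),
            tree_ops.bm_covariance(sub))


def pgls_pair(trait_x: str, trait_y: str, table: TraitTable, tree,
              lambda_mode: str = "mean_of_trait_MLEs",
              lam_fixed: float | None = None,
              subset: str = "all") -> TraitPairResult | None:
    """OLS and PGLS between two traits (response = `trait_y`).

    The default lambda policy averages the two per-trait ML estimates and
    caps the mean at 1; ``joint_ML`` instead profiles lambda on the
    residuals of the pair model, and ``fixed`` uses `lam_fixed`.
    Returns None (with a log note) when fewer than 10 shared tips remain.
    """
    if not table.log_space:
        raise ValueError("pairwise regressions expect the log-space table")
    aligned = _aligned_pair(trait_x, trait_y, table, tree)
    if aligned is None:
        logger.warning("pgls_pair(%s, %s): insufficient overlap, skipped",
                       trait_x, trait_y)
        return None
    x, y, C = aligned

    if lambda_mode == "mean_of_trait_MLEs":
        lx = PagelLambda().fit(C, x).lambda_
        ly = PagelLambda().fit(C, y).lambda_
        lam = min(1.0, 0.5 * (lx + ly))
    elif lambda_mode == "joint_ML":
        lam = _joint_ml_lambda(y, np.column_stack([np.ones_like(x), x]), C)
    elif lambda_mode == "fixed":
        if lam_fixed is None:
            raise ValueError("lam_fixed required for lambda_mode='fixed'")
        lam = float(lam_fixed)
    else:
        raise ValueError(f"unknown lambda_mode {lambda_mode!r}")

    design = np.column_stack([np.ones_like(x), x])
    names = ["const", trait_x]
    ols = fit_gls(y, design, V=None, names=names, lambda_used=0.0)
    V = tree_ops.lambda_transform(C, lam).to_numpy()
    pgls = fit_gls(y, design, V=V, names=names, lambda_used=lam)
    if lam < 1e-8 and np.ptp(np.diag(C.to_numpy())) < 1e-8 * np.diag(C).mean():
        # self-check: star-tree PGLS must coincide with OLS
        assert np.allclose(pgls.params, ols.params, atol=1e-10)
    return TraitPairResult(trait_x, trait_y, ols, pgls, lam, subset=subset)


def _joint_ml_lambda(y, X, C) -> float:
    """Profile lambda on the residual likelihood of the pair model."""
    A = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C, float)
    lmax = tree_ops.lambda_max(A)
    D = np.diag(np.diag(A))
    off = A - D

    def nll(lam):
        V = lam * off + D
        c, logdet = chol(V)
        iX, iy = solve(c, X), solve(c, y)
        beta = np.linalg.solve(X.T @ iX, X.T @ iy)
        e = y - X @ beta
        rss = float(e @ solve(c, e))
        n = len(y)
        s2 = max(rss / n, 1e-300)
        return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

    grid = np.linspace(0, lmax * (1.0 - 1e-6), 25)
    vals = [nll(l) for l in grid]
    k = int(np.argmin(vals))
    from scipy.optimize import minimize_scalar
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        return min(1.0, float(res.x))
    return min(1.0, float(grid[k]))


DEFAULT_PAIR_TRAITS = ("sco", "kcatc", "kc", "kc_air", "ko")


def pairwise_matrix(table: TraitTable, tree, traits=DEFAULT_PAIR_TRAITS,
                    subset: str = "all",
                    lambda_mode: str = "mean_of_trait_MLEs") -> pd.DataFrame:
    """All unordered trait pairs as a tidy grid of OLS/PGLS percentages."""
    traits = [t for t in traits if t in table.traits]
    if len(traits) < 2:
        raise ValueError("need at least two traits")
    rows = []
    for i, tx in enumerate(traits):
        for ty in traits[i + 1:]:
            res = pgls_pair(tx, ty, table, tree, lambda_mode=lambda_mode,
                            subset=subset)
            if res is None:
                rows.append({"trait_x": tx, "trait_y": ty, "subset": subset,
                             "note": "skipped: insufficient overlap"})
                continue
            rows.append({
                "trait_x": tx, "trait_y": ty, "subset": subset,
                "n": res.ols.n, "lambda_pair": res.lambda_pair,
                "ols_pct": res.variance_explained_ols,
                "ols_alpha": res.alpha_ols,
                "pgls_pct": res.variance_explained_pgls,
                "pgls_alpha": res.alpha_pgls,
                "ols_slope": res.ols.slope, "pgls_slope": res.pgls.slope,
            })
    return pd.DataFrame(rows)


def group_compare(table: TraitTable, trait: str,
                  groups: tuple[str, str] = ("C3", "C4")) -> dict:
    """Two-group location and spread comparison for one trait.

    Welch's t-test and the Brown-Forsythe (median-centered) Levene test
    run on the table's current space; group means and 95 % CIs are always
    reported in raw measurement units (back-transformed if the table is
    log space).
    """
    g1, g2 = groups
    vals = {}
    for g in groups:
        v = table.data.loc[table.data["ptype"] == g, trait].dropna().to_numpy(float)
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values for {trait}")
        vals[g] = v
    t_stat, t_p = stats.ttest_ind(vals[g1], vals[g2], equal_var=False)
    lev_stat, lev_p = stats.levene(vals[g1], vals[g2], center="median")
    out = {"trait": trait, "groups": groups,
           "t_stat": float(t_stat), "t_p": float(t_p),
           "levene_stat": float(lev_stat), "levene_p": float(lev_p)}
    for g, v in vals.items():
        raw = np.exp(v) if table.log_space else v
        m = float(raw.mean())
        half = stats.t.ppf(0.975, len(raw) - 1) * raw.std(ddof=1) / np.sqrt(len(raw))
        out[f"mean_{g}"] = m
        out[f"ci_{g}"] = (m - float(half), m + float(half))
        out[f"n_{g}"] = int(len(raw))
    return out


def pgls_group_contrast(table: TraitTable, trait: str, tree,
                        groups: tuple[str, str] = ("C3", "C4")) -> RegressionFit:
    """Phylogenetically corrected group contrast.

    Fits ``trait ~ indicator(photosynthetic type)`` by GLS with the
    lambda-transformed covariance (lambda from the trait's ML estimate,
    capped at 1).  The contrast p-value is the indicator coefficient's.
    """
    df = table.data.set_index("species")
    mask = df["ptype"].isin(groups) & df[trait].notna()
    keep = df.index[mask]
    shared = [l for l in tree_ops.tip_labels(tree) if l in set(keep)]
    sub = tree_ops.prune_to(tree, shared)
    labels = tree_ops.tip_labels(sub)
    y = df.loc[labels, trait].to_numpy(float)
    levels = sorted(set(df.loc[labels, "ptype"]))
    if len(levels) < 2:
        raise ValueError("photosynthetic type has a single level in the subset")
    C = tree_ops.bm_covariance(sub)
    lam = min(1.0, PagelLambda().fit(C, y).lambda_)
    V = tree_ops.lambda_transform(C, lam).to_numpy()
    dummies = np.column_stack(
        [(df.loc[labels, "ptype"] == lv).to_numpy(float) for lv in levels[1:]])
    design = np.column_stack([np.ones(len(y)), dummies])
    names = ["const"] + [f"ptype[{lv}]" for lv in levels[1:]]
    return fit_gls(y, design, V=V, names=names, lambda_used=lam)
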