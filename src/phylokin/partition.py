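"""Variance partitioning via predictive partial R^2.

For each kinetic trait, a full phylogenetic regression model is compared
with reduced models that drop either the phylogenetic covariance (star
tree: independent tips with depth-proportional variances) or one kinetic
predictor.  Predictions are tip-wise conditional expectations under the
fitted covariance:

    yhat_i = x_i beta + V_{i,-i} V_{-i,-i}^{-1} (y_{-i} - X_{-i} beta)

and ``partial R^2_pred = 1 - SSE_full / SSE_reduced`` (floored at 0).
The phylogenetic component for a trait uses intercept-only models; each
trade-off component compares ``trait ~ predictor`` against ``trait ~ 1``
with the same lambda-transformed covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tree_ops
from ._gls import chol, solve
from .signal import PagelLambda
from .trait_data import TraitTable


def conditional_predictions(y, X, V, beta=None) -> np.ndarray:
    """Tip-wise conditional means under a fitted GLS model.

    Uses the precision-matrix identity: with ``P = V^-1`` and residuals
    ``e = y - X beta``, the conditional residual mean for tip i given all
    others is ``e_i - (P e)_i / P_ii``, so no per-tip matrix partitioning
    is needed.  `beta` defaults to the GLS estimate under V.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    V = np.asarray(V, dtype=float)
    c, _ = chol(V)
    if beta is None:
        iX, iy = solve(c, X), solve(c, y)
        beta = np.linalg.solve(X.T @ iX, X.T @ iy)
    e = y - X @ beta
    P = solve(c, np.eye(len(y)))
    return y - (P @ e) / np.diag(P)


def r2_pred(y, X, V) -> float:
    """Predictive R^2: 1 - sum (y - yhat)^2 / sum (y - ybar)^2.

    With a diagonal V and a constant diagonal this reduces to the
    ordinary predictive R^2 of the linear fit; it can be negative.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = conditional_predictions(y, X, V)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - sse / sst


def partial_r2_pred(y, X_full, V_full, X_red, V_red) -> float:
    """Partial predictive R^2 of a nested model comparison, floored at 0."""
    y = np.asarray(y, dtype=float).ravel()
    sse_full = float(np.sum((y - conditional_predictions(y, X_full, V_full)) ** 2))
    sse_red = float(np.sum((y - conditional_predictions(y, X_red, V_red)) ** 2))
    if sse_red <= 0:
        return 0.0
    return max(0.0, 1.0 - sse_full / sse_red)


@dataclass(frozen=True)
class PartitionResult:
    trait: str
    phylo_component: float            # percent
    tradeoff_components: dict         # predictor -> percent
    lambda_used: float
    n: int
    subset: str = "all"


def partition_trait(trait: str, table: TraitTable, tree,
                    predictors, subset: str = "all") -> PartitionResult:
    """Partition one trait's variance into phylogenetic and trade-off parts.

    The phylogenetic component compares an intercept-only model with the
    lambda-transformed covariance against the same model on the star
    covariance (its diagonal).  Each trade-off component adds one kinetic
    predictor to the intercept model, holding the covariance fixed.
    Percentages are partial; they need not sum to 100.
    """
    yv = table.trait_vector(trait)
    shared = [l for l in tree_ops.tip_labels(tree) if l in yv.index]
    sub = tree_ops.prune_to(tree, shared)
    labels = tree_ops.tip_labels(sub)
    y = yv.loc[labels].to_numpy(float)
    C = tree_ops.bm_covariance(sub)
    lam = min(1.0, PagelLambda().fit(C, y).lambda_)
    V = tree_ops.lambda_transform(C, lam).to_numpy()
    star = np.diag(np.diag(C.to_numpy()))
    ones = np.ones((len(y), 1))

    phylo = 100.0 * partial_r2_pred(y, ones, V, ones, star)

    tradeoffs = {}
    df = table.data.set_index("species")
    for pred in predictors:
        if pred == trait or pred not in table.traits:
            continue
        x = df.loc[labels, pred]
        mask = x.notna().to_numpy()
        if mask.sum() < 10:
            continue
        sub2 = tree_ops.prune_to(sub, [l for l, m in zip(labels, mask) if m])
        labs2 = tree_ops.tip_labels(sub2)
        y2 = yv.loc[labs2].to_numpy(float)
        C2 = tree_ops.bm_covariance(sub2)
        lam2 = min(1.0, PagelLambda().fit(C2, y2).lambda_)
        V2 = tree_ops.lambda_transform(C2, lam2).to_numpy()
        X_full = np.column_stack([np.ones(len(y2)),
                                  df.loc[labs2, pred].to_numpy(float)])
        tradeoffs[pred] = 100.0 * partial_r2_pred(
            y2, X_full, V2, np.ones((len(y2), 1)), V2)

    return PartitionResult(trait=trait, phylo_component=phylo,
                           tradeoff_components=tradeoffs, lambda_used=lam,
                           n=len(y), subset=subset)


def cumulative_summary(results: list[PartitionResult],
                       mode: str = "mean") -> tuple[float, float]:
    """Aggregate per-trait components into one (phylo %, trade-off %) pair.

    Modes: ``mean`` (default; per-trait components averaged, trade-offs
    first averaged within trait), ``sum``, and ``variance_weighted``
    (weights proportional to n, a proxy for the information per trait).
    """
    if not results:
        raise ValueError("no partition results to aggregate")
    phylo = np.array([r.phylo_component for r in results], float)
    trade = np.array([np.mean(list(r.tradeoff_components.values()))
                      if r.tradeoff_components else 0.0 for r in results], float)
    if mode == "mean":
        return float(phylo.mean()), float(trade.mean())
    if mode == "sum":
        return float(phylo.sum()), float(trade.sum())
    if mode == "variance_weighted":
        w = np.array([r.n for r in results], float)
        w = w / w.sum()
        return float(phylo @ w), float(trade @ w)
    raise ValueError(f"unknown mode {mode!r}")


def partition_frame(results: list[PartitionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"trait": r.trait, "subset": r.subset, "n": r.n,
               "lambda": r.lambda_used, "phylo_pct": r.phylo_component}
        for pred, pct in r.tradeoff_components.items():
            row[f"tradeoff_{pred}_pct"] = pct
        rows.append(row)
    return pd.DataFrame(rows)
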