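"""Brownian-motion ancestral state estimation for internal nodes.

Each internal node's estimate is the conditional expectation of that
node's state given the tip values under the fitted BM model:

    ahat_v = mu + c_v' C^{-1} (y - mu 1)

where ``mu`` is the GLS phylogenetic mean, ``C`` the tip covariance and
``c_v[i]`` the root-ward path length shared between node v and tip i.
The root estimate is ``mu`` itself; every estimate is a convex
combination of tip values.  Estimation is at lambda = 1 (plain BM) by
default; a lambda-transformed reconstruction is available via `lam`.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from . import tree_ops
from ._gls import chol, gls_mean, solve


@dataclass(frozen=True)
class AncestralStates:
    trait: str
    states: dict          # node id -> estimate (root included)
    root: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.states), "estimate": list(self.states.values()),
             "trait": self.trait})


def ancestral_states_bm(y, tree: dendropy.Tree, trait: str = "trait",
                        lam: float = 1.0) -> AncestralStates:
    """GLS (ML under BM) ancestral estimates for every internal node.

    `y` is a mapping/Series keyed by tip label, complete on the tree's
    tips.  Internal nodes are labelled ``node<k>`` in preorder when the
    tree carries no internal labels.
    """
    labels = tree_ops.tip_labels(tree)
    yv = pd.Series(y).reindex(labels)
    if yv.isna().any():
        raise ValueError("trait values required for every tip")
    yarr = yv.to_numpy(float)
    C = tree_ops.bm_covariance(tree)
    if float(np.diag(C).max()) <= 0:
        raise ValueError("tree has zero depth")
    Cm = tree_ops.lambda_transform(C, lam).to_numpy()
    c, _ = chol(Cm)
    mu = gls_mean(yarr, c)
    alpha = solve(c, yarr - mu)

    depth = tree_ops._node_depths(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    # any descendant tip of each node, for shared-path lookup
    rep_tip: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            rep_tip[node] = idx[node.taxon.label]
        else:
            rep_tip[node] = rep_tip[node.child_nodes()[0]]

    states: dict[str, float] = {}
    k = 0
    under: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            under[node] = [idx[node.taxon.label]]
        else:
            under[node] = [i for ch in node.child_nodes() for i in under[ch]]
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        name = node.label or f"node{k}"
        k += 1
        # shared path with tips below v is depth(v); otherwise the
        # covariance of any tip below v with the outside tip
        cv = C.to_numpy()[rep_tip[node], :].copy()
        cv[under[node]] = depth[node]
        states[name] = float(mu + lam * cv @ alpha)
    root_name = next(iter(states))
    return AncestralStates(trait=trait, states=states, root=states[root_name])


def annotate_tree(tree: dendropy.Tree, anc: AncestralStates) -> str:
    """Newick with ancestral estimates as internal node comments."""
    out = tree.clone(depth=1)
    k = 0
    for node in out.preorder_node_iter():
        if node.is_leaf():
            continue
        name = node.label or f"node{k}"
        k += 1
        node.annotations.add_new("anc", f"{anc.states[name]:.6g}")
    return out.as_string(schema="newick", suppress_rooting=True,
                         unquoted_underscores=True,
                         suppress_annotations=False)
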