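"""Tree parsing and the matrices every downstream statistic consumes.

All comparative statistics in this package are driven by one of three
tip-by-tip matrices derived from a rooted, branch-lengthed tree:

* the Brownian-motion covariance ``C`` (shared root-to-tip path lengths),
* the patristic distance matrix ``d`` and its reciprocal Moran weights,
* the topology-only Abouheif proximity (path products of 1/child-count).

Branch-length transforms (Pagel's lambda, star collapse) act on ``C``.
Trees are handled with dendropy; polytomies are supported natively.
"""

from __future__ import annotations

import io
import logging

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .trait_data import TraitTable, ValidationError

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    pass


def read_newick(source) -> dendropy.Tree:
    """Parse a rooted, branch-lengthed Newick tree.

    `source` is a path or a Newick string.  Trees without branch lengths
    are rejected: every statistic here needs path lengths.  Tip labels
    must be unique; underscores are preserved as-is.
    """
    kwargs = dict(schema="newick", preserve_underscores=True)
    text = str(source)
    try:
        if text.strip().startswith("(") and text.strip().endswith(";"):
            tree = dendropy.Tree.get(data=text, **kwargs)
        else:
            tree = dendropy.Tree.get(path=text, **kwargs)
    except Exception as err:  # dendropy raises reader-specific subclasses
        if "Duplicate" in str(err) or "duplicate" in str(err):
            raise TreeError(f"duplicate tip labels: {err}") from err
        raise
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeError("tree has edges without branch lengths")
        if edge.length < 0:
            raise TreeError("negative branch length")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: dendropy.Tree) -> dict:
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    return depth


def bm_covariance(tree: dendropy.Tree) -> pd.DataFrame:
    """Brownian-motion tip covariance: C_ij = depth of the MRCA of i and j.

    Computed in one postorder sweep: at each internal node, every pair of
    tips drawn from two different child subtrees has that node as its MRCA.
    """
    depth = _node_depths(tree)
    labels = tip_labels(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            below[node] = [i]
            C[i, i] = depth[node]
        else:
            groups = [below.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ii = np.asarray(groups[a])[:, None]
                    jj = np.asarray(groups[b])[None, :]
                    C[ii, jj] = d
                    C[jj.T, ii.T] = d
            below[node] = [i for g in groups for i in g]
    return pd.DataFrame(C, index=labels, columns=labels)


def lambda_max(C: pd.DataFrame | np.ndarray) -> float:
    """Largest lambda keeping the transformed covariance valid.

    min over tips i of C_ii / max_{j != i} C_ij; for an ultrametric tree
    this sits slightly above 1.
    """
    A = np.asarray(C, dtype=float)
    off = A - np.diag(np.diag(A))
    row_max = off.max(axis=1)
    with np.errstate(divide="ignore"):
        ratios = np.where(row_max > 0, np.diag(A) / row_max, np.inf)
    return float(ratios.min())


def lambda_transform(C: pd.DataFrame, lam: float) -> pd.DataFrame:
    """Multiply off-diagonal covariance entries by lambda.

    lambda = 0 collapses to the star phylogeny (independent tips with
    depth-proportional variances); lambda = 1 is the identity.
    """
    lmax = lambda_max(C)
    if lam < 0 or lam > lmax + 1e-12:
        raise ValueError(f"lambda={lam} outside [0, lambda_max={lmax:.6g}]")
    A = np.asarray(C, dtype=float)
    out = lam * A + (1.0 - lam) * np.diag(np.diag(A))
    if isinstance(C, pd.DataFrame):
        return pd.DataFrame(out, index=C.index, columns=C.columns)
    return out


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip path lengths, via d_ij = C_ii + C_jj - 2 C_ij."""
    C = bm_covariance(tree)
    depths = np.diag(C.values)
    d = depths[:, None] + depths[None, :] - 2.0 * C.values
    np.fill_diagonal(d, 0.0)
    d[np.abs(d) < 1e-12] = np.abs(d[np.abs(d) < 1e-12])  # clip -0.0
    return pd.DataFrame(d, index=C.index, columns=C.columns)


def moran_weights(d: pd.DataFrame, row_normalize: bool = True) -> pd.DataFrame:
    """Reciprocal-distance proximity weights for Moran's I.

    Zero off-diagonal distances are rejected: byte-identical sequences must
    be condensed to single tips before autocorrelation weights exist.
    Row normalization (default) scales each row to sum 1; the resulting
    matrix is generally asymmetric and used as-is by the statistic.
    """
    D = np.asarray(d, dtype=float)
    off = ~np.eye(len(D), dtype=bool)
    if np.any(D[off] <= 0):
        raise ValidationError(
            "zero patristic distance between distinct tips; run "
            "condense_identical_tips first")
    W = np.zeros_like(D)
    W[off] = 1.0 / D[off]
    if row_normalize:
        W = W / W.sum(axis=1, keepdims=True)
    return pd.DataFrame(W, index=d.index, columns=d.columns)


def abouheif_proximity(tree: dendropy.Tree) -> pd.DataFrame:
    """Topology-only proximity: product over internal nodes on the i-j path
    of 1 / (number of children of that node).  Branch lengths are ignored,
    so the matrix is invariant to any rescaling of the tree.
    """
    labels = tip_labels(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    # ancestors of each tip from parent up to root, with child counts
    anc: dict[int, list[tuple]] = {}
    for leaf in tree.leaf_node_iter():
        chain = []
        node = leaf.parent_node
        while node is not None:
            chain.append((node, len(node.child_nodes())))
            node = node.parent_node
        anc[idx[leaf.taxon.label]] = chain
    A = np.zeros((n, n))
    for i in range(n):
        anc_i = anc[i]
        set_i = {id(nd) for nd, _ in anc_i}
        for j in range(i + 1, n):
            anc_j = anc[j]
            mrca = next(nd for nd, _ in anc_j if id(nd) in set_i)
            prod = 1.0
            for nd, dd in anc_i:
                prod /= dd
                if nd is mrca:
                    break
            for nd, dd in anc_j:
                if nd is mrca:
                    break
                prod /= dd
            A[i, j] = A[j, i] = prod
    return pd.DataFrame(A, index=labels, columns=labels)


def prune_to(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Return a copy of the tree retaining only the given tip labels."""
    pruned = tree.clone(depth=1)
    keep = set(labels)
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    pruned.retain_taxa(taxa)
    return pruned


def read_fasta(source) -> dict[str, str]:
    """FASTA records as an id -> uppercase sequence mapping."""
    text = str(source)
    handle = io.StringIO(text) if text.lstrip().startswith(">") else text
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def condense_identical_tips(table: TraitTable, alignment: dict[str, str],
                            tree: dendropy.Tree):
    """Merge tips whose aligned sequences are byte-identical.

    Species carrying identical marker-gene sequences sit on zero-length
    terminal branches and carry no phylogenetic information of their own,
    so each identity group collapses to a single data point: the
    alphabetically first label survives, kinetic values are per-trait
    arithmetic means over the group's non-missing measurements, and the
    tree is pruned to the surviving tips.

    Returns ``(table, tree, n_groups)``.
    """
    labels = tip_labels(tree)
    missing = [l for l in labels if l not in alignment]
    if missing:
        raise ValidationError(f"alignment records missing for tips: {missing[:5]}")
    groups: dict[str, list[str]] = {}
    for lab in labels:
        groups.setdefault(alignment[lab], []).append(lab)
    merged = {min(g): sorted(g) for g in groups.values()}
    n_groups = sum(1 for g in merged.values() if len(g) > 1)
    if n_groups == 0:
        return table, tree, 0

    df = table.data.copy()
    rep = {m: keep for keep, g in merged.items() for m in g}
    df = df[df["species"].isin(rep)].copy()
    df["species"] = df["species"].map(rep)
    traits = [t for t in table.traits]
    meta = [c for c in df.columns if c not in traits and c != "species"]
    agg = {t: "mean" for t in traits}
    agg.update({c: "first" for c in meta})
    out = df.groupby("species", sort=False, as_index=False).agg(agg)
    n_removed = len(labels) - len(merged)
    note = (f"condense_identical_tips: {n_groups} identity groups, "
            f"{len(labels)} -> {len(merged)} tips")
    logger.info(note)
    new_table = table._with(out, note)
    new_tree = prune_to(tree, list(merged))
    return new_table, new_tree, n_groups


def synonymous_site_filter(alignment: dict[str, str]) -> dict[str, str]:
    """Drop codon columns where any two sequences encode different residues.

    The alignment must be codon-aware (length divisible by 3, frame at
    column 1, standard genetic code).  A codon containing gaps counts as a
    mismatch unless it is entirely gaps, in which case that sequence is
    ignored for the column.
    """
    seqs = list(alignment.values())
    if not seqs:
        return {}
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValidationError("alignment sequences differ in length")
    if length % 3:
        raise ValidationError(f"alignment length {length} not divisible by 3")
    keep: list[int] = []
    for start in range(0, length, 3):
        aas = set()
        ok = True
        for s in seqs:
            codon = s[start:start + 3]
            if codon == "---":
                continue
            if "-" in codon:
                ok = False
                break
            aas.add(str(Seq(codon).translate()))
            if len(aas) > 1:
                ok = False
                break
        if ok and len(aas) <= 1:
            keep.append(start)
    return {name: "".join(s[p:p + 3] for p in keep)
            for name, s in alignment.items()}
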