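"""Synthetic trees, traits, and fixture bundles.

The generator emulates the statistical structure of a comparative rubisco
kinetics dataset: an ultrametric species tree, log-scale kinetic traits
evolving by correlated Brownian motion with per-trait phylogenetic signal
lambda, a C4 kinetic syndrome (lower specificity, faster carboxylation,
weaker CO2 affinity, inflated K_O spread) painted onto a few clades,
duplicate species entries, two specificity assay families bridged by a
wheat standard, and groups of byte-identical marker sequences.

Trait means come from the measured C3 angiosperm averages, per-trait
lambdas from the angiosperm signal estimates, and the C4 shift vector
from the measured C4/C3 mean ratios; dispersions and rates are realistic
choices documented in the methods note.

The trait model: for trait t with signal ``lam_t``, log-values are

    mu_t + sigma_t * ( sqrt(lam_t) B_t + sqrt(1 - lam_t) W_t )

where the Brownian components B and white components W are each
correlated across traits by the increment-correlation matrix rho.  The
implied cross-trait covariance matches ``rho_st * sigma_s * sigma_t``
times a lambda-blended tree covariance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import tree_ops
from .trait_data import TraitTable


@dataclass(frozen=True)
class TraitSpec:
    lam: float          # phylogenetic signal in [0, 1]
    mu_log: float       # mean on the natural-log scale
    sigma_log: float    # dispersion on the natural-log scale


def _default_traits() -> dict:
    return {
        # lambdas: angiosperm signal estimates; means: ln of C3 means
        "sco": TraitSpec(0.879, float(np.log(89.9)), 0.10),
        "kcatc": TraitSpec(0.968, float(np.log(3.2)), 0.35),
        "kc": TraitSpec(0.902, float(np.log(15.4)), 0.40),
        # K_O carries signal among C3 species; the C4 syndrome masks it
        "ko": TraitSpec(0.743, float(np.log(481.0)), 0.18),
        "krubp": TraitSpec(0.5, float(np.log(25.0)), 0.30),
    }


def _default_rho() -> np.ndarray:
    # increment correlations; kcatc-kc 0.55 gives the ~30% PGLS trade-off
    order = ["sco", "kcatc", "kc", "ko", "krubp"]
    r = np.eye(len(order))

    def put(a, b, v):
        i, j = order.index(a), order.index(b)
        r[i, j] = r[j, i] = v

    put("sco", "kcatc", -0.28)
    put("sco", "kc", -0.25)
    put("kcatc", "kc", 0.55)
    put("kc", "ko", 0.29)
    return r


def _default_delta() -> dict:
    # ln of the measured C4/C3 mean ratios
    return {
        "sco": float(np.log(78.7 / 89.9)),
        "kcatc": float(np.log(4.2 / 3.2)),
        "kc": float(np.log(19.0 / 15.4)),
        "ko": 0.0,
    }


@dataclass
class SimulationConfig:
    """Study-scale defaults: 137 angiosperm tips, ~15 % C4 in a few clades,
    18 identical-sequence cherry pairs, two specificity assay families."""

    n_tips: int = 137
    birth: float = 1.0
    traits: dict = field(default_factory=_default_traits)
    rho: np.ndarray = field(default_factory=_default_rho)
    c4_fraction: float = 21.0 / 137.0
    c4_clades: int = 3
    delta: dict = field(default_factory=_default_delta)
    ko_inflation: float = 3.0       # variance factor on C4 K_O residuals
    n_c3c4: int = 6
    n_c4like: int = 3
    ko_decouple: bool = False       # redraw C4 K_O independent of the tree
    duplicate_fraction: float = 0.08
    identical_pairs: int = 18
    krubp_n: int = 19
    electrode_fraction: float = 0.45
    wheat_reference: float = 100.0
    seq_length: int = 1398          # rbcL-like coding length
    seq_mut_rate: float = 0.08      # substitutions / site / unit depth
    seed: int = 0

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        if not np.allclose(rho, rho.T) or np.any(np.diag(rho) != 1):
            raise ValueError("rho must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(rho).min() < -1e-10:
            raise ValueError("rho must be positive semi-definite")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def simulate_yule_tree(n_tips: int, birth: float = 1.0,
                       seed: int = 0) -> dendropy.Tree:
    """Pure-birth ultrametric tree, rescaled to unit root-to-tip depth.

    Same seed, same Newick string.
    """
    if n_tips < 3 or birth <= 0:
        raise ValueError("need n_tips >= 3 and birth > 0")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    birth_time = {tree.seed_node: 0.0}
    active = []
    for _ in range(2):  # root splits at time zero
        ch = tree.seed_node.new_child()
        birth_time[ch] = 0.0
        active.append(ch)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth * len(active)))
        node = active.pop(rng.integers(len(active)))
        for _ in range(2):
            ch = node.new_child()
            birth_time[ch] = t
            active.append(ch)
    t_end = t + rng.exponential(1.0 / (birth * len(active)))
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        end = t_end if node.is_leaf() else birth_time[node.child_nodes()[0]]
        node.edge.length = (end - birth_time[node]) / t_end
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"sp{i:03d}")
    return tree


def simulate_traits(tree: dendropy.Tree, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> TraitTable:
    """Correlated lambda-blended Brownian traits on the tree (raw units)."""
    rng = rng or np.random.default_rng(config.seed)
    C = tree_ops.bm_covariance(tree).to_numpy()
    labels = tree_ops.tip_labels(tree)
    n, p = len(labels), len(config.traits)
    rho = np.asarray(config.rho, dtype=float)
    L_rho = np.linalg.cholesky(rho + 1e-12 * np.eye(p))
    L_C = np.linalg.cholesky(C + 1e-10 * np.mean(np.diag(C)) * np.eye(n))
    B = L_C @ rng.standard_normal((n, p)) @ L_rho.T
    W = (np.sqrt(np.diag(C))[:, None] * rng.standard_normal((n, p))) @ L_rho.T
    data = {"species": labels, "group": "angiosperm", "ptype": "C3",
            "sco_method": "gas_phase", "source_id": "gasref"}
    for j, (name, spec) in enumerate(config.traits.items()):
        logv = spec.mu_log + spec.sigma_log * (
            np.sqrt(spec.lam) * B[:, j] + np.sqrt(1.0 - spec.lam) * W[:, j])
        data[name] = np.exp(logv)
    return TraitTable(pd.DataFrame(data), log_space=False,
                      provenance=(f"simulated: n={n} seed={config.seed}",))


def _pick_clades(tree, target: int, n_clades: int, rng) -> list[list[str]]:
    """Disjoint clades whose tip counts sum to ~target (within +-50 %)."""
    nodes = [(node, [l.taxon.label for l in node.leaf_iter()])
             for node in tree.preorder_internal_node_iter()
             if node is not tree.seed_node]
    nodes = [(nd, tips) for nd, tips in nodes if 2 <= len(tips) <= target]
    order = rng.permutation(len(nodes))
    chosen: list[list[str]] = []
    used: set[str] = set()
    total = 0
    for k in order:
        nd, tips = nodes[k]
        if used & set(tips):
            continue
        if total + len(tips) > 1.5 * target:
            continue
        chosen.append(tips)
        used |= set(tips)
        total += len(tips)
        if len(chosen) >= n_clades and total >= 0.5 * target:
            break
    if not (0.5 * target <= total <= 1.5 * target):
        raise ValueError(
            f"could not cover ~{target} tips with {n_clades} clades (got {total})")
    return chosen


def inject_c4_regime(tree: dendropy.Tree, table: TraitTable,
                     config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> TraitTable:
    """Paint the C4 kinetic syndrome onto a few clades.

    Selected clades get the log-scale shift vector delta (specificity
    down, turnover and K_C up), K_O residual variance inflated by
    ``ko_inflation``, and ptype relabelled C4.  A handful of additional
    tips become C3-C4 / C4-like intermediates carrying only the
    specificity shift.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    if not 0 < config.c4_fraction <= 0.5:
        raise ValueError("c4_fraction must be in (0, 0.5]")
    df = table.data.copy().set_index("species")
    target = max(2, round(config.c4_fraction * len(df)))
    clades = _pick_clades(tree, target, config.c4_clades, rng)
    c4_tips = [t for clade in clades for t in clade if t in df.index]
    for trait, d in config.delta.items():
        if trait in df.columns and d != 0.0:
            df.loc[c4_tips, trait] *= float(np.exp(d))
    if "ko" in df.columns and len(c4_tips) > 1:
        lk = np.log(df.loc[c4_tips, "ko"].to_numpy(float))
        if config.ko_decouple:
            # convergent variability: K_O redrawn independent of the tree
            resid = lk.std(ddof=1) * rng.standard_normal(len(lk))
            df.loc[c4_tips, "ko"] = np.exp(
                lk.mean() + np.sqrt(config.ko_inflation) * resid)
        elif config.ko_inflation != 1.0:
            df.loc[c4_tips, "ko"] = np.exp(
                lk.mean() + np.sqrt(config.ko_inflation) * (lk - lk.mean()))
    df.loc[c4_tips, "ptype"] = "C4"
    rest = [s for s in df.index if s not in set(c4_tips)]
    inter = rng.choice(rest, size=min(config.n_c3c4 + config.n_c4like, len(rest)),
                       replace=False)
    for i, sp in enumerate(inter):
        df.loc[sp, "ptype"] = "C3-C4" if i < config.n_c3c4 else "C4-like"
        if "sco" in df.columns:
            df.loc[sp, "sco"] *= float(np.exp(config.delta.get("sco", 0.0)))
    out = df.reset_index()
    return table._with(
        out, f"inject_c4_regime: {len(c4_tips)} C4 tips in {len(clades)} clades")


def _simulate_sequences(tree, length, rate, rng) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    root = rng.integers(0, 4, size=length)
    seqs: dict[str, np.ndarray] = {}
    state = {tree.seed_node: root}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = state[node.parent_node]
        seq = parent.copy()
        n_mut = rng.poisson(rate * length * (node.edge.length or 0.0))
        if n_mut:
            pos = rng.integers(0, length, size=n_mut)
            seq[pos] = (seq[pos] + rng.integers(1, 4, size=n_mut)) % 4
        state[node] = seq
        if node.is_leaf():
            seqs[node.taxon.label] = seq
    return {k: "".join(bases[v]) for k, v in seqs.items()}


def make_fixture_bundle(config: SimulationConfig, outdir) -> dict:
    """Emit a complete synthetic input bundle for the pipeline.

    Writes ``traits.csv`` (duplicate rows, electrode/gas-phase assay split
    with per-study wheat bias, sparse K_RuBP), ``tree.nwk``,
    ``alignment.fasta`` (with identical-sequence cherry pairs) and
    ``wheat_standards.json``.  Returns the paths plus the generated
    objects; every file records the seed in a comment header.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    r_tree, r_traits, r_c4, r_noise, r_seq = [
        np.random.default_rng(s) for s in master.spawn(5)]

    tree = simulate_yule_tree(config.n_tips, config.birth, seed=config.seed)
    table = simulate_traits(tree, config, rng=r_traits)
    table = inject_c4_regime(tree, table, config, rng=r_c4)
    df = table.data.copy()

    # sparse K_RuBP
    keep = set(r_noise.choice(df["species"], size=min(config.krubp_n, len(df)),
                              replace=False))
    df.loc[~df["species"].isin(keep), "krubp"] = np.nan

    # assay families with a wheat-standard bias on electrode studies
    studies = ["study_A", "study_B", "study_C"]
    wheat = {s: float(config.wheat_reference * np.exp(r_noise.normal(0, 0.05)))
             for s in studies}
    is_elec = r_noise.random(len(df)) < config.electrode_fraction
    src = r_noise.choice(studies, size=len(df))
    df.loc[is_elec, "sco_method"] = "electrode"
    df.loc[is_elec, "source_id"] = src[is_elec]
    bias = np.array([wheat[s] / config.wheat_reference for s in src])
    df.loc[is_elec, "sco"] = df.loc[is_elec, "sco"] * bias[is_elec]

    # duplicate rows (slightly jittered remeasurements)
    n_dup = int(round(config.duplicate_fraction * len(df)))
    if n_dup:
        dup_sp = r_noise.choice(df["species"], size=n_dup, replace=False)
        dups = df[df["species"].isin(dup_sp)].copy()
        for col in ("sco", "kcatc", "kc", "ko", "krubp"):
            dups[col] = dups[col] * np.exp(r_noise.normal(0, 0.05, len(dups)))
        df = pd.concat([df, dups], ignore_index=True)
        df = df.sample(frac=1.0, random_state=int(config.seed % 2**31)
                       ).reset_index(drop=True)

    # sequences with forced identical cherry pairs
    seqs = _simulate_sequences(tree, config.seq_length, config.seq_mut_rate,
                               r_seq)
    cherries = [nd for nd in tree.preorder_internal_node_iter()
                if all(ch.is_leaf() for ch in nd.child_nodes())
                and len(nd.child_nodes()) == 2]
    if len(cherries) < config.identical_pairs:
        raise ValueError(f"only {len(cherries)} cherries for "
                         f"{config.identical_pairs} identical pairs")
    pick = r_seq.choice(len(cherries), size=config.identical_pairs,
                        replace=False)
    for k in pick:
        a, b = [ch.taxon.label for ch in cherries[k].child_nodes()]
        seqs[b] = seqs[a]
    # guard against accidental cross-group collisions
    seen: dict[str, str] = {}
    forced = {seqs[l] for k in pick
              for l in [ch.taxon.label for ch in cherries[k].child_nodes()]}
    for lab in sorted(seqs):
        s = seqs[lab]
        if s in seen and s not in forced:
            alt = ("A" if s[0] != "A" else "C") + s[1:]
            seqs[lab] = alt
        seen[seqs[lab]] = lab

    paths = {
        "traits": outdir / "traits.csv",
        "tree": outdir / "tree.nwk",
        "alignment": outdir / "alignment.fasta",
        "wheat": outdir / "wheat_standards.json",
    }
    with open(paths["traits"], "w") as fh:
        fh.write(f"# synthetic fixture bundle, seed={config.seed}\n")
        df.to_csv(fh, index=False)
    tree_ops.write_newick(tree, paths["tree"])
    with open(paths["alignment"], "w") as fh:
        for lab in sorted(seqs):
            fh.write(f">{lab}\n{seqs[lab]}\n")
    with open(paths["wheat"], "w") as fh:
        json.dump({"reference": config.wheat_reference, "by_study": wheat,
                   "seed": config.seed}, fh, indent=1)
    return {**{k: str(v) for k, v in paths.items()},
            "tree_obj": tree, "table_obj": table, "n_rows": len(df)}


def config_to_json(config: SimulationConfig) -> str:
    d = dataclasses.asdict(config)
    d["rho"] = np.asarray(config.rho).tolist()
    d["traits"] = {k: dataclasses.asdict(v) for k, v in config.traits.items()}
    return json.dumps(d, indent=1, sort_keys=True)
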