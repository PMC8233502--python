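"""End-to-end orchestration: trait preparation, signal panels, pairwise
regressions, variance partitioning and ancestral states for each
configured species subset, with a machine-readable run manifest.

Given identical inputs, config and seed, the report bundle is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import scipy

from . import __version__, ancestral, partition, pgls, signal, trait_data, tree_ops

logger = logging.getLogger(__name__)

SUBSETS = ("angiosperms_all", "C3_only", "all_organisms", "exclude_C4_lineage")


@dataclass
class PipelineConfig:
    traits_csv: str
    tree_file: str
    alignment_fasta: str | None = None
    wheat_json: str | None = None
    subsets: tuple = ("angiosperms_all", "C3_only")
    traits: tuple = ("sco", "kcatc", "kc", "kc_air", "ko")
    n_perm: int = 999
    seed: int = 0
    lambda_mode: str = "mean_of_trait_MLEs"
    row_normalize: bool = True
    cumulative_mode: str = "mean"
    outdir: str = "phylokin_out"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.subsets:
            raise ValueError("at least one subset must be configured")
        bad = set(self.subsets) - set(SUBSETS)
        if bad:
            raise ValueError(f"unknown subsets: {sorted(bad)}")


def _canon(name: str) -> str:
    return "_".join(str(name).strip().split()).replace(" ", "_")


def _subset_mask(table: trait_data.TraitTable, subset: str) -> pd.Series:
    pt = table.data["ptype"]
    if subset in ("angiosperms_all", "all_organisms"):
        return pd.Series(True, index=table.data.index)
    if subset == "C3_only":
        return pt == "C3"
    if subset == "exclude_C4_lineage":
        return ~pt.isin(["C3-C4", "C4-like", "C4"])
    raise ValueError(subset)


def prepare_inputs(config: PipelineConfig):
    """Stages up to the analysis-ready (table, tree): load, normalize,
    collapse duplicates, derive kc_air, complete-case filter, condense
    identical-sequence tips, log transform, and name matching."""
    table = trait_data.load_trait_table(config.traits_csv)
    if config.wheat_json:
        wheat = json.loads(Path(config.wheat_json).read_text())
        table = trait_data.normalize_sco(table, wheat["reference"],
                                         wheat["by_study"])
    table = trait_data.collapse_duplicates(table)
    table = trait_data.add_kc_air(table)
    table = trait_data.complete_case_filter(
        table, trait_data.PRINCIPAL_TRAITS,
        group="angiosperm" if "group" in table.data.columns else None)
    tree = tree_ops.read_newick(config.tree_file)
    n_groups = 0
    if config.alignment_fasta:
        aln = tree_ops.read_fasta(config.alignment_fasta)
        table, tree, n_groups = tree_ops.condense_identical_tips(
            table, aln, tree)
    table = trait_data.log_transform(table)

    # exact matching after whitespace/underscore canonicalization
    df = table.data.copy()
    df["species"] = df["species"].map(_canon)
    table = table._with(df, "canonicalized species names")
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = _canon(leaf.taxon.label)
    tips = set(tree_ops.tip_labels(tree))
    species = set(table.species)
    unmatched = {"table_only": sorted(species - tips),
                 "tree_only": sorted(tips - species)}
    shared = sorted(species & tips)
    if not shared:
        raise ValueError("no species shared between table and tree")
    table = table.subset(table.data["species"].isin(shared),
                         f"matched to tree: {len(shared)} species")
    tree = tree_ops.prune_to(tree, shared)
    return table, tree, {"unmatched": unmatched, "n_shared": len(shared),
                         "n_condensed_groups": n_groups}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for every configured subset; write the report.

    Returns the in-memory report dict; CSV tables and ``manifest.json``
    are written under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, tree, match_info = prepare_inputs(config)
    report: dict = {"tables": {}}
    stage = "prepare"
    try:
        for subset in config.subsets:
            stage = f"{subset}"
            sub_table = table.subset(_subset_mask(table, subset), f"subset {subset}")
            shared = sub_table.species
            sub_tree = tree_ops.prune_to(tree, shared)
            traits = [t for t in config.traits if t in sub_table.traits]

            sig_cfg = signal.SignalConfig(n_perm=config.n_perm,
                                          seed=config.seed,
                                          row_normalize=config.row_normalize)
            panels = [signal.signal_panel(t, sub_table, sub_tree, sig_cfg)
                      for t in traits]
            report["tables"][f"signal_{subset}"] = signal.panel_frame(panels)

            report["tables"][f"pairwise_{subset}"] = pgls.pairwise_matrix(
                sub_table, sub_tree, traits=traits, subset=subset,
                lambda_mode=config.lambda_mode)

            parts = [partition.partition_trait(
                t, sub_table, sub_tree,
                predictors=[u for u in traits if u != t], subset=subset)
                for t in traits]
            pframe = partition.partition_frame(parts)
            cum = {m: partition.cumulative_summary(parts, mode=m)
                   for m in ("mean", "sum", "variance_weighted")}
            report["tables"][f"partition_{subset}"] = pframe
            report.setdefault("cumulative", {})[subset] = {
                m: {"phylo_pct": v[0], "tradeoff_pct": v[1]}
                for m, v in cum.items()}

            anc_rows = []
            for t in traits:
                yv = sub_table.trait_vector(t)
                tips_t = [l for l in tree_ops.tip_labels(sub_tree)
                          if l in yv.index]
                anc_tree = tree_ops.prune_to(sub_tree, tips_t)
                a = ancestral.ancestral_states_bm(yv, anc_tree, trait=t)
                anc_rows.append(a.frame())
            report["tables"][f"ancestral_{subset}"] = pd.concat(
                anc_rows, ignore_index=True)

            if subset in ("angiosperms_all", "all_organisms"):
                counts = sub_table.data["ptype"].value_counts()
                if counts.get("C3", 0) >= 2 and counts.get("C4", 0) >= 2:
                    rows = []
                    for t in traits:
                        gc = pgls.group_compare(sub_table, t)
                        fit = pgls.pgls_group_contrast(sub_table, t, sub_tree)
                        contrast_p = float(fit.pvalues.iloc[1])
                        rows.append({
                            "trait": t, "t_stat": gc["t_stat"],
                            "t_p": gc["t_p"],
                            "t_alpha": signal.alpha_bin(gc["t_p"]),
                            "levene_stat": gc["levene_stat"],
                            "levene_p": gc["levene_p"],
                            "levene_alpha": signal.alpha_bin(gc["levene_p"]),
                            "mean_C3": gc["mean_C3"], "mean_C4": gc["mean_C4"],
                            "ci_C3_lo": gc["ci_C3"][0], "ci_C3_hi": gc["ci_C3"][1],
                            "ci_C4_lo": gc["ci_C4"][0], "ci_C4_hi": gc["ci_C4"][1],
                            "pgls_contrast_p": contrast_p,
                            "pgls_contrast_alpha": signal.alpha_bin(contrast_p),
                            "pgls_lambda": fit.lambda_used,
                        })
                    report["tables"][f"group_contrast_{subset}"] = pd.DataFrame(rows)
    except Exception as err:
        manifest = {"status": "error", "failed_stage": stage, "error": str(err),
                    "tables_completed": sorted(report["tables"])}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    for name, frame in report["tables"].items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
    cfg = dataclasses.asdict(config)
    manifest = {
        "status": "ok",
        "phylokin_version": __version__,
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__,
                     "dendropy": dendropy.__version__},
        "seed": config.seed,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "match_info": match_info,
        "n_species": len(table),
        "provenance": list(table.provenance),
        "cumulative": report.get("cumulative", {}),
        "tables": sorted(report["tables"]),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    report["manifest"] = manifest
    return report
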