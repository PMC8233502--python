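# phylokin

Phylogenetically resolved comparative analysis of enzyme kinetic traits,
built around the question of what limits the evolution of rubisco: the
enzyme's internal catalytic trade-offs, or phylogenetic constraint — the
tendency of related species to carry similar kinetics simply by descent.

The package is aimed at comparative enzymologists and molecular
evolution researchers who have (1) a species-level table of kinetic
traits — CO2/O2 specificity *S*<sub>C/O</sub>, carboxylase turnover
*k*<sub>catC</sub>, and the Michaelis constants *K*<sub>C</sub>,
*K*<sub>O</sub>, *K*<sub>RuBP</sub> — and (2) a rooted, branch-lengthed
species tree (e.g. from *rbcL*). It provides:

* **Trait preparation** — cross-assay normalization of specificity via a
  shared wheat standard, duplicate collapsing to per-trait medians,
  derivation of *K*<sub>C</sub><sup>air</sup> = *K*<sub>C</sub> (1 +
  [O2]/*K*<sub>O</sub>) with [O2] = 253 µM, complete-case filtering, and a
  natural-log transform.
* **Phylogenetic signal detection** — five detectors run as a panel:
  Pagel's λ (ML, likelihood-ratio test), Blomberg's *K* and *K**
  (permutation test), Moran's *I* and Abouheif's
  *C*<sub>mean</sub> (autocorrelation with permutation tests); a trait is
  called "signal present" when ≥ 3 of 5 detectors reach *p* < 0.05.
* **PGLS trade-off quantification** — generalized least squares with
  error covariance σ²C(λ), where C is the Brownian-motion tip covariance
  and λ rescales its off-diagonal (λ per pair = mean of the two trait
  MLEs, capped at 1). Variance explained is reported as 100 R² for both
  OLS and PGLS, so phylogeny-naive and phylogeny-aware estimates are
  directly comparable.
* **Variance partitioning** — predictive partial R²
  (R²<sub>pred</sub>) comparisons of nested phylogenetic regressions,
  separating the percentage of each trait's variance explained by the
  tree itself from that explained by each catalytic trade-off.
* **C3/C4 contrasts** — Welch *t* and Brown–Forsythe Levene tests between
  photosynthetic types, with phylogenetically corrected contrasts
  (photosynthetic type as a GLS factor).
* **Ancestral states** — BM/GLS conditional-expectation estimates for
  every internal node.
* **A synthetic-data generator** — ultrametric Yule trees, correlated
  λ-blended Brownian traits, C4 regime shifts painted onto clades,
  duplicate rows, two specificity assay families, and identical-sequence
  tip groups — so the entire pipeline is testable without any downloads.

Core model: a trait vector y on n species follows
y ~ N(μ1, σ² C(λ)), with C<sub>ij</sub> the shared root-ward path length
of tips i and j and C(λ) multiplying the off-diagonal by λ. λ = 0 is a
star phylogeny (independent tips), λ = 1 plain Brownian motion. All
regressions, partitions and ancestral estimates are GLS computations
under this covariance.

## Worked example

```python
import phylokin as pk

# a 137-species synthetic study: tree, traits, C4 clades, assay structure
config = pk.SimulationConfig(seed=42)
bundle = pk.make_fixture_bundle(config, "example")

pipeline = pk.PipelineConfig(
    traits_csv=bundle["traits"], tree_file=bundle["tree"],
    alignment_fasta=bundle["alignment"], wheat_json=bundle["wheat"],
    seed=42, outdir="example_report")
report = pk.run_pipeline(pipeline)

print(report["tables"]["signal_angiosperms_all"]
      [["trait", "n", "lambda_stat", "lambda_alpha", "cmean_stat",
        "cmean_alpha", "presence"]].to_string(index=False))
pw = report["tables"]["pairwise_angiosperms_all"]
row = pw[(pw.trait_x == "kcatc") & (pw.trait_y == "kc")].iloc[0]
print(f"\nkcatc ~ kc: OLS {row.ols_pct:.1f}% ({row.ols_alpha}), "
      f"PGLS {row.pgls_pct:.1f}% ({row.pgls_alpha}), "
      f"lambda_pair {row.lambda_pair:.3f}")
cum = report["manifest"]["cumulative"]["angiosperms_all"]["mean"]
print(f"cumulative: phylogeny {cum['phylo_pct']:.1f}% vs "
      f"trade-offs {cum['tradeoff_pct']:.1f}%")
```

Output:

```
 trait   n  lambda_stat lambda_alpha  cmean_stat cmean_alpha  presence
   sco 119     0.771323        0.001    0.630525        0.01      True
 kcatc 119     0.995051        0.001    0.868764        0.01      True
    kc 119     0.910310        0.001    0.673887        0.01      True
kc_air 119     0.906127        0.001    0.666428        0.01      True
    ko 119     0.652066        0.001    0.403210        0.01      True

kcatc ~ kc: OLS 61.6% (0.001), PGLS 29.8% (0.001), lambda_pair 0.953
cumulative: phylogeny 63.8% vs trade-offs 19.1%
```

Reading it: the generator drew 137 species (119 after condensing
identical-sequence tips) with strong per-trait phylogenetic signal, so
every trait's panel comes back "present". The *k*<sub>catC</sub> ~
*K*<sub>C</sub> regression illustrates the central phenomenon: ordinary
least squares reports 61.6 % shared variance, but over half of that is
shared ancestry — the phylogenetic regression (λ = 0.953) leaves a
29.8 % trade-off, close to the generating increment correlation
(ρ² = 0.30). The cumulative partition says the tree explains more trait
variance than all pairwise trade-offs combined.

The same analyses are available from the shell:

```bash
phylokin simulate --seed 42 --outdir example
phylokin run-all --traits example/traits.csv --tree example/tree.nwk \
    --alignment example/alignment.fasta --wheat example/wheat_standards.json \
    --seed 42 --subset angiosperms_all --subset C3_only --outdir example_report
```

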