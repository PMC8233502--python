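# Methods

## Model

All statistics derive from the Brownian-motion (BM) tip covariance of a
rooted, branch-lengthed species tree: C_ij is the branch length shared
by the root-to-tip paths of species i and j, C_ii the depth of tip i.
A trait vector y (natural-log scale) is modelled as

    y ~ N(mu 1, sigma^2 C(lambda)),     C(lambda) = lambda C + (1 - lambda) diag(C)

Pagel's lambda interpolates between a star phylogeny (lambda = 0,
independent tips with depth-proportional variances) and plain BM
(lambda = 1). The admissible upper bound is
lambda_max = min_i C_ii / max_{j != i} C_ij, which keeps C(lambda)
positive semi-definite; for ultrametric trees it sits slightly above 1,
so maximum-likelihood estimates marginally above 1 are representable.
Polytomies are handled natively by every matrix construction; no random
resolution is performed.

## Trait preparation

The pipeline order is fixed and recorded in the table's provenance:
specificity normalization -> duplicate collapsing -> K_C^air derivation
-> complete-case filtering -> identical-sequence condensation -> log
transform. Rationale for the order: normalization must see the original
per-study rows; medians are taken over raw measurements; K_C^air
(K_C (1 + [O2]/K_O), dissolved [O2] = 253 uM for 20.95 % air, exposed as
a config constant) is derived record-wise before any aggregation in log
space; condensation means are arithmetic means of raw values (geometric
means would result if taken after the log transform). The log transform
is natural-log; every downstream statistic (R^2, signal statistics,
t tests) is invariant to the base up to scale. Medians over an even
number of duplicates use the conventional mean-of-central-values
definition. Missing values are propagated, never imputed; pairwise
analyses use pairwise deletion per trait pair.

Specificity values measured with O2-electrode assays are multiplied by
(reference wheat S_C/O) / (that study's wheat S_C/O), bringing them onto
the gas-phase assay scale; gas-phase rows define the reference frame and
are untouched. The operation is idempotent (guarded by provenance) and
commutes with duplicate collapsing only when duplicates share a source
study, which is why the order is asserted.

## Signal detectors

* **Pagel's lambda (ML).** The profiled log-likelihood
  l(lambda) = -1/2 [n ln(2 pi sigma_hat^2) + ln|C(lambda)| + n], with
  mu and sigma^2 profiled analytically, is maximized by a 25-point
  coarse grid over [0, lambda_max) followed by bounded scalar
  refinement (tolerance 1e-6) around the best grid point; the grid stage
  doubles as a multi-start guard against local optima. The search stops
  just inside lambda_max because C(lambda_max) is exactly singular.
  Singular intermediate matrices fall back to a 1e-10 relative ridge
  with a logged warning. Significance is a likelihood-ratio test against
  lambda = 0. Because the null pins the parameter to its boundary, the
  default reference is the 50:50 chi2_0/chi2_1 mixture; plain chi2_1 is
  available (`chisq_mode="chi2"`) and is conservative. Even the mixture
  is finite-sample conservative on ~100-tip trees (measured type-I
  ~0.02 at nominal 0.05); this is a property of the test, not a defect —
  the implementation reproduces an independent reference implementation's
  lambda, log-likelihood and LRT to six significant digits.
* **Blomberg's K and K*.** K is the observed ratio MSE0/MSE — MSE0 the
  mean squared deviation about the GLS (phylogenetic) mean, MSE the
  BM-whitened mean squared error — divided by its BM expectation
  [tr(C) - n / (1'C^-1 1)]/(n - 1), so E[K] ~ 1 under BM. K* centers
  MSE0 on the arithmetic mean instead. Significance is a tip-shuffling
  permutation test on the whitened MSE (small MSE = strong signal);
  K and K* share the permutation p-value because both use the same MSE.
* **Moran's I / Abouheif's C_mean.** The autocorrelation form
  I = (n/S0) z'Wz / z'z with z = y - ybar. Moran weights default to
  row-normalized reciprocal patristic distances (the common proximity
  choice for this test family; the raw reciprocal matrix is available
  via `row_normalize=False` since the choice is not canonical), and the
  resulting asymmetric W is used as-is. C_mean uses the topology-only
  Abouheif proximity: the product over internal nodes on the i-j path of
  1/(child count), invariant to branch-length rescaling. Both tests are
  one-sided toward positive autocorrelation, matching the direction a
  heritable trait produces. Zero patristic distances (byte-identical
  sequences) must be removed by condensation before weights exist.

Permutation p-values are (1 + #{perm >= observed}) / (n_perm + 1), so
the smallest attainable p is 1/(n_perm + 1); the default n_perm = 999
gives a floor of 0.001. Permutation streams are seeded per detector from
a spawned seed sequence, so panels are bit-reproducible. Alpha binning
uses strict inequalities (p < 0.001 / 0.01 / 0.05, else ns); boundary
values fall into the weaker bin, so the permutation floor 0.001 reports
as the 0.01 bin — a deliberate, conservative boundary convention.

A trait's "signal present" call is the majority vote: at least 3 of the
5 detectors significant at 0.05.

## Regression and partitioning

GLS fits use Cholesky whitening; R^2 = 1 - RSS/TSS with both sums in the
whitened metric and TSS about the GLS intercept-only mean, reported as a
percentage for direct OLS/PGLS comparison. Coefficient tests are t with
n - k degrees of freedom. The per-pair lambda policy averages the two
per-trait ML estimates and caps at 1 (joint residual-ML and fixed-lambda
modes are available for sensitivity analysis). Regressions are
direction-ordered (response = second-named trait); OLS percentages are
symmetric in the pair, PGLS percentages can differ by direction under
joint ML, which is why the default policy uses the symmetric mean-MLE
lambda. With lambda < 1e-8 on an ultrametric tree the PGLS fit is
asserted equal to OLS as a running self-check. Pairs with fewer than 10
shared tips are skipped with an annotation. Regressions default to the
condensed (identical-sequence-merged) table because PGLS needs the
pruned tree; without a tree only OLS is meaningful.

Predictive R^2 uses tip-wise conditional expectations under the fitted
covariance: yhat_i = x_i beta + V_{i,-i} V_{-i,-i}^{-1}(y_{-i} -
X_{-i} beta), computed for all tips at once via the precision-matrix
identity yhat = y - (P e)/diag(P), P = V^-1 — the full-conditional
construction, not leave-one-out refitting of beta. Partial
R^2_pred = 1 - SSE_full/SSE_reduced, floored at 0 (predictive R^2 can be
negative; components are reported as explained variance). The
phylogenetic component of a trait compares intercept-only models under
C(lambda_hat) and under the star covariance diag(C) — the natural
"no phylogeny" nesting of the lambda error model; each trade-off
component adds one kinetic predictor to the intercept model at fixed
covariance. Cumulative summaries are reported under three aggregation
modes side by side — mean (headline; the only mode bounded like the
per-trait components), sum, and n-weighted mean.

Group contrasts: Welch's t (the unflagged default two-sample test) and
the Brown–Forsythe Levene test (median-centered; centering is
configurable) on the table's current space; group means and 95 % CIs are
always back-transformed to raw measurement units. The phylogenetically
corrected contrast fits trait ~ indicator(photosynthetic type) by GLS
with the trait's capped lambda MLE.

Ancestral states are BM/GLS conditional expectations
a_v = mu + c_v' C^{-1}(y - mu 1), with c_v the shared root-ward path of
node v with each tip; the root estimate is the GLS mean itself and every
estimate is a convex combination of tip values. Estimation is at
lambda = 1 (plain BM) by default, the standard choice for painting
reconstructions onto a tree; a lambda-transformed variant is available.

## Synthetic data

The generator emulates the statistical structure of a curated rubisco
kinetics study; its defaults are the study conditions, fixed once:

* 137 species on a unit-depth Yule tree (birth rate 1.0 — only relative
  times matter after rescaling), reduced to 119 by 18 identical-sequence
  cherry pairs; 19 species carry K_RuBP; ~8 % duplicate rows; ~45 % of
  specificity rows come from three simulated O2-electrode studies whose
  wheat standards are drawn around the gas-phase reference (±5 % log
  scale).
* Per-trait signal lambdas from the angiosperm estimates (S_C/O 0.879,
  k_catC 0.968, K_C 0.902; K_O 0.743 — its C3-level signal); log-scale
  means are the logs of the measured C3 group means (89.9 mol/mol,
  3.2 /s, 15.4 uM, 481 uM); log-scale SDs (0.10, 0.35, 0.40, 0.18) are
  realistic dispersions chosen once to match the spread of published
  kinetic compilations.
* Trait correlations are imposed on the Brownian increments (shared
  tree, correlated innovations) — the generative analogue of a true
  catalytic trade-off, so OLS-vs-PGLS contrasts are meaningful by
  construction. Default increment correlations: k_catC–K_C 0.55
  (rho^2 ~ 0.30, the magnitude of the phylogeny-robust trade-off),
  S_C/O–k_catC -0.28, S_C/O–K_C -0.25, K_C–K_O 0.29.
* The C4 syndrome: ~15 % of tips in 3 clades (multiple independent
  origins) get log-scale shifts equal to the measured C4/C3 mean ratios
  (S_C/O x0.875, k_catC x1.31, K_C x1.23), K_O residual variance
  inflated 3-fold (from the measured C3 vs C4 interval widths), plus 6
  C3–C4 and 3 C4-like intermediates carrying the specificity shift only.
  An optional decoupled mode redraws C4 K_O independent of the tree
  (convergent variability); with it, full-set K_O signal statistics are
  attenuated relative to the C3-only subset — the mechanism behind a
  K_O signal detectable only among C3 species — though a full flip to
  non-significance additionally requires the weaker signal level of
  real K_O data.
* Sequences are a root string of rbcL-like length (1398 nt) mutated
  Poisson-wise along branches; only identity/non-identity matters for
  the condensation machinery, so no codon model is used.

What the generator does not emulate: measurement error structure beyond
log-normal jitter on duplicates, non-ultrametric (substitutions/site)
branch lengths, codon-level sequence realism, and taxon sampling bias.
Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed generative model, not robustness to every
feature of real kinetic compilations.

## Numerical choices and limitations

* Cholesky everywhere; exactly-singular matrices get a 1e-10 relative
  ridge with a logged warning.
* Seeds are mandatory in every stochastic component; identical
  (inputs, config, seed) produce bit-identical report bundles.
* Species matching between table and tree is exact after
  whitespace/underscore canonicalization; unmatched names are listed in
  the run manifest, never silently dropped.
* Problem sizes in the test and acceptance studies (100–200 tips,
  199–999 permutations, 40–500 replicates) were chosen as the smallest
  sizes at which the calibration and recovery claims are statistically
  sharp.
* Known limitations: no OU or early-burst alternatives to the lambda/BM
  error family; no confidence intervals on ancestral states; no
  standardized major-axis regression; the lambda LRT is finite-sample
  conservative (see above), so lambda significance calls on ~100-tip
  trees are slightly cautious.
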