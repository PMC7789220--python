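# Methods

`momicnet` integrates up to three omics tables measured on the same
samples by reducing each table to co-expression modules, summarising each
module by one profile per sample, and testing associations between those
profiles across layers and against external sample parameters. This note
documents the models and conventions the package implements, the
parameters that matter, and what the synthetic benchmark does and does not
establish.

## Per-layer weighted correlation networks

For one layer with samples × features matrix X:

1. **Correlation.** Pearson (default) or Spearman feature–feature
   correlation `r_ij`; zero-variance features are rejected by name.
2. **Soft-thresholded adjacency.** Unsigned `a_ij = |r_ij|^β` (default) or
   signed `a_ij = ((1+r_ij)/2)^β`, β ≥ 1.
3. **Power selection.** For each candidate β (default grid 1–10, 12–24 in
   steps of 2), the connectivities `k_i = Σ_{j≠i} a_ij` are binned into 10
   equal-width bins (empty bins dropped) and log10(bin frequency) is
   regressed on log10(mean bin connectivity). The signed fit index is
   `−sign(slope)·R²`, so degree distributions that *increase* with k score
   negatively. The chosen β is the smallest candidate reaching
   `r2_target` (default 0.8); if none does, the best-fitting β is used with
   a warning, and a degenerate fit (all degrees equal) chooses nothing. The
   "bin center" is the mean connectivity within the bin, the convention of
   the classical fit index; arithmetic midpoints change the fit only
   marginally.
4. **Topological overlap.** `TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`
   with `ℓ_ij = Σ_{u≠i,j} a_iu a_uj`; TOM ∈ [0,1], diagonal 1.
5. **Module detection.** Average-linkage hierarchical clustering of
   `1 − TOM` with a static cut at `cut_height × (max merge height)`;
   clusters below `min_module_size` become label 0 ("grey"), the rest are
   renumbered by decreasing size. The default `cut_height = 0.9999` is
   deliberately close to 1: at the powers the scale-free scan typically
   selects (β ≈ 12–24), topological overlap is compressed toward zero and
   *all* merge heights crowd into the last ~10⁻³ below 1 — module joins
   remain clearly above within-module merges, but only a cut in that last
   sliver separates them. A conventional 0.99 cut leaves every feature a
   singleton there. The trade-off: with few samples (n ≲ 40) and low power
   (β ≈ 6), noise features can correlate strongly enough by chance to merge
   below the cut; use the automatic power scan, more samples, or a lower
   `cut_height` in that regime. The dynamic tree-cut family of algorithms
   is intentionally out of scope.
6. **Eigengenes.** Each module's eigengene is the first left singular
   vector of its standardized (z-scored per feature) sample × feature
   block, scaled to unit variance and sign-aligned so it correlates
   nonnegatively with the module's mean standardized profile. Modules whose
   eigengenes are closer than `merge_cut` (default 0.25 on the 1 − r scale)
   are merged iteratively, recomputing eigengenes after every merge.
7. **Module–trait report.** Quantitative traits are correlated directly;
   qualitative traits are expanded to one 0/1 indicator per level
   (point-biserial correlation) rather than integer-coded, because integer
   codes impose an arbitrary level order. p-values come from
   `t = r√(n−2)/√(1−r²)` on n−2 df; Benjamini–Hochberg correction is
   applied over the whole module × trait-column grid. Constant columns
   report NaN and are excluded from the correction.

Outlier screening before network construction standardizes each sample's
summed affinity `((1+r)/2)²` to all other samples and reports samples with
z below `z_cut` (default −2.5). Note the false-flag rate implied by a −2.5
cut: on homogeneous Gaussian data with 50 samples about 0.3 samples per
dataset exceed it by chance, so flags are reported, never auto-removed.

## Cross-layer integration

Module eigengenes from different layers are correlated pairwise (never
within a layer); because each layer contributes only a handful of
eigengenes, the number of tests stays small and power high. BH correction
runs jointly over all inter-layer pairs. Edges with q ≤ α (default 0.05)
form the multilayer graph; unassigned features (module 0) never
participate. Isolated modules are kept only if their own anchor-trait
association passes α. For a qualitative anchor trait each module is
annotated with the indicator level of largest |r|. The hive layout places
one axis per layer at 120° spacing and orders modules radially by
anchor-trait correlation (rank scaled to (0,1], ties by module id).
A selected module pair can be expanded to a bipartite feature network:
all member features correlated two-by-two (Spearman default, threshold
default 0.35 on |r|), with per-edge p/q attached so users can post-filter;
the edge rule itself is magnitude-only.

## Ordination

* **PCA/PCoA.** PCA uses uniform row weights 1/n (eigenvalues `s²/n`), the
  multi-table convention, so that the self-co-inertia identity below is
  exact. PCoA double-centres `−½D²`; negative eigenvalues are reported,
  and the optional constant-shift correction finds, by bisection, the
  smallest additive constant on off-diagonal distances that makes the
  spectrum nonnegative. Axis signs everywhere follow "largest-|loading|
  element positive".
* **Co-inertia (2 tables).** SVD of `X'Y` for centred tables; the axis-k
  covariance is `s_k/n`, and for Y = X the pseudo-eigenvalues equal the
  squared PCA eigenvalues. Drivers are features ranked by |loading|.
* **Multiple co-inertia (2–3 tables).** Tables are centred and scaled to
  unit total inertia; per axis, unit weight vectors `w_k` maximise
  `Σ_{k<l} cov²(X_k w_k, X_l w_l)` by alternating power updates
  (deterministic merged-table SVD initialisation, weight-change tolerance
  1e-10, ≤ 500 iterations, deflation of each table by its own weight
  between axes). This pairwise-covariance dialect was chosen over the
  sum-of-operators (compromise-eigenvector) formulation because only the
  pairwise form reduces *exactly* to co-inertia analysis with two tables —
  the compromise eigenproblem mixes in within-table variance and provably
  breaks that identity. The reference (consensus) scores are computed
  post hoc per axis as the direction maximising the summed squared
  covariance with the table scores. Per-table scores are the triangle
  vertices of the co-inertia plot.
* **Procrustes / PROTEST.** Optimal translation + scaling + rotation of
  configuration b onto a; `m² = 1 − (Σσ)²/(tr A'A · tr B'B)` on the centred
  configurations, in [0,1] and symmetric in the inputs. The permutation
  test permutes the rows of b (`p = (1 + #{m²_perm ≤ m²_obs})/(N+1)`,
  default N = 999, mandatory seed).

## OPLS / OPLS-DA validation

Module-versus-trait validation fits orthogonal PLS with exactly one
predictive component (single-trait usage) after `n_orth` (default 1)
orthogonal-signal-correction steps in NIPALS form: per step, the loading of
the current predictive score is split into its y-related and y-orthogonal
parts and the orthogonal component is removed from X. X is standardized
internally; quantitative y is centred and scaled, qualitative y is
dummy-coded and centred only, with the predictive weight taken from the
first singular vector of `X'Y`. With one predictive component the VIP
formula collapses to `VIP_j = √p · |w_j|/‖w‖`, so `Σ VIP² = p` identically.
Q² uses seeded k-fold cross-validation (default 7 folds, stratified by
class for qualitative traits), `Q² = 1 − PRESS/SSY`. Note that with
standardized features a single PLS component leaks ~(p−1)/n of the response
variance into noise directions, so R²Y approaches 1 only when n ≫ p even
for a noiseless linear response.

## Synthetic data

The generator plants a one-factor block model per module:
`x_ij = λ_j f_i + ε_ij` with ε ~ N(0, noise_sd²), λ ~ U[0.8, 1.2] rescaled
so the expected within-module correlation `λ²/(λ²+σ²)` hits the target.
Defaults state the benchmark world: 60 samples, 150 features per layer,
three modules of 40 (so 30 pure-noise background features — these give the
network its heavy-tailed degree distribution), within-module correlation
0.7, unit noise. Cross-layer structure comes from factor groups whose
member modules draw correlated copies (`corr·g + √(1−corr²)·e`) of one
group factor; quantitative traits are linear in factors plus noise,
qualitative traits threshold a factor at level quantiles. `make_null`
keeps the per-layer module structure but makes all factors independent
across layers and traits independent of everything, for FDR and type-I
checks. A multinomial sampler (softmax of latent values, fixed depth per
sample) produces compositional count layers for the CLR path.

What the generator does *not* emulate: overdispersed sequencing noise,
batch effects, heavy-tailed feature distributions, correlated noise, or
unequal module sizes within a layer. Green recovery tests therefore
establish correctness of the machinery under the factor model, not
robustness to real-data pathologies.

## Numerical conventions and degenerate inputs

* CLR pseudocount: 0 if all values positive, else 1 for integer counts or
  half the minimum positive value for real tables; rows sum to 0 within
  1e-10.
* Prevalence filtering keeps ties at the threshold (≥) and uses strict
  "> 0" presence.
* Correlation p-values clip |r| = 1 to p = 0; BH passes NaN through.
* All randomness (permutation tests, cross-validation folds, generators)
  flows through explicit integer seeds via `numpy.random.default_rng`.

## Known limitations

* Static-height module detection (see trade-off above); no dynamic tree
  cut, no consensus networks, no block-wise decomposition for very large
  feature sets.
* At most three layers; module matching across layers is by eigengene
  correlation only, never by shared feature identifiers.
* MCIA axes beyond the first are locally optimal (alternating ascent); for
  two tables they are globally optimal via the SVD equivalence.
* OPLS supports a single predictive component; multi-block variants and
  sparse discriminant analysis are out of scope.
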