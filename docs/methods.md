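# Methods

## Enrichment-score abundance estimation

The enrichment score of a signature set S against a ranked gene list L of
length N is the running-sum statistic of the weighted Kolmogorov–Smirnov
form: walking down L, the sum rises by |r_j|^α / N_R at members of S
(N_R = Σ_{g∈S} |r_j|^α) and falls by 1/(N − N_H) otherwise; the ES is the
deviation of greatest magnitude, signed, and lies in [−1, 1]. ES = 1 exactly
when all members occupy the top N_H ranks; a bottom-loaded set mirrors to
−1. When the deviation's maximum magnitude is attained at several indices,
the earliest index is taken; exact ties can be broken differently by
floating-point rounding, which is why the test oracle compares magnitudes
exactly and signs only when the exact-arithmetic winner is unique.

Two ranking modes exist because abundance estimation and phenotype analysis
rank differently:

* **per-sample** (the reproduction path, default): genes ranked by
  expression within one sample, weight α = 0.25 (the single-sample GSEA
  convention). The ES of an immune-cell signature is that cell's relative
  abundance in the sample. Ties break by gene ID so results are
  bit-reproducible.
* **two-class**: genes ranked by the signal-to-noise statistic
  (μ₁−μ₀)/(σ₁+σ₀), each class standard deviation floored at 0.2·|μ|
  (0.2 when μ = 0), weight α = 1. Each class needs ≥ 2 samples.

No permutation normalization is applied by default — raw ES is reported as
abundance; a seeded gene-shuffle permutation null is available
(`gsea.permutation_pvalues`) but off (0 permutations). Signature genes
absent from the expression matrix are dropped with their counts recorded:
the only workable policy when signatures and platforms differ.

## Pearson screen

All peripheral × CSF pairs are tested with the exact small-sample t
reference for the Pearson correlation. Selection keeps any peripheral
variable with ≥ 1 p < α cell (α = 0.05). No multiplicity correction is
applied by default — the screen deliberately reproduces a raw-α selection
rule, which at 34×3 tests admits roughly 1−0.95³ ≈ 14% of null variables;
the null-calibration test quantifies exactly this. `correct="bh"` switches
the matrix to Benjamini–Hochberg-adjusted p-values. Constant variables are
undefined under Pearson correlation and are excluded with a warning rather
than imputed or dropped silently.

## Canonical correlation analysis

Blocks are column-standardized (n−1 variance); the canonical structure is
computed from the SVD of the whitened cross-correlation matrix
K = R_xx^{−1/2} R_xy R_yy^{−1/2} rather than the generalized eigenproblem —
the two are algebraically equivalent and the SVD route is numerically
stable and guarantees orthonormal variates. Coefficients are standardized
(a_i = R_xx^{−1/2} u_i), so each variate has unit variance.

Numerical choices:

* **Rank deficiency.** A block whose correlation matrix has an eigenvalue
  below 1e−10 is rejected with the likely collinear columns named; a ridge
  (suggested 1e−8) can be requested explicitly and is logged.
* **Sign convention.** CCA is sign-indeterminate per function. The pair
  (a_k, b_k) is flipped jointly so the variable with the largest-magnitude
  loading across both blocks loads positively; flipping jointly keeps
  r_k ≥ 0. Comparisons against other software should be made up to a global
  sign per function.
* **Sequential tests.** For function k, Wilks Λ_k = Π_{i≥k}(1−r_i²) is
  referred to Rao's F with dimensions shrunk by k−1 in both blocks
  (p_k = p−k+1, q_k = q−k+1, t = √((p_k²q_k²−4)/(p_k²+q_k²−5)), t = 1 in the
  degenerate cases, df1 = p_k q_k,
  df2 = t[(n−1)−(p_k+q_k+1)/2] − df1/2 + 1). For p_k = q_k = 1 this reduces
  exactly to the squared Pearson t test, which the suite cross-checks.
  Function-1 statistics match standard statistical-package output exactly;
  conventions for the n-adjustment of later roots differ slightly across
  packages, so rows k > 1 should be compared approximately. Λ numerically
  zero (a perfect canonical correlation, e.g. duplicated blocks) is
  reported as F = ∞, p = 0 rather than an error.
* **Derived quantities.** Loadings are R_xx a_k (identically the correlation
  of each variable with its own variate); cross-loadings are r_k · loading;
  the redundancy index RI_k = r_k² · mean(loading²) equals the mean squared
  cross-loading. These identities are asserted at 1e−10 in the suite.

Requirements: n > p + q and full column rank. The pipeline truncates an
over-large screened set (possible at the α = 1 boundary) to the smallest
screen p-values so the CCA stays identified, with a warning.

## ROC and logistic combination

AUC is the Mann–Whitney probability that a random case outranks a random
control, ties credited ½ (computed via scikit-learn; an exhaustive
pair-counting oracle lives in the tests). Markers are scored as given and
reported both raw and orientation-corrected (max(a, 1−a)), since the
case-like direction of a marker (e.g. a cell type reduced in disease) is a
reporting convention. The logistic combination is a maximum-likelihood fit
(Newton/IRLS, tolerance 1e−8 on the score, ≤ 100 iterations) with Wald
z/p per coefficient — the convention of standard packages — and an
inclusion check at p < 0.1 that warns rather than refits. Perfect
separation (unbounded likelihood, detected by the optimizer or by
|β| > 50) and non-convergence are hard errors for direct calls; the
pipeline degrades gracefully to single-marker reporting. A zero-variance
feature leaves the likelihood flat in one direction; the fit falls back to
L-BFGS with a warning and that Wald entry is undefined. AUCs are apparent
(resubstitution) estimates by default, matching how such small-cohort
analyses are usually reported; `loo=True` computes leave-one-out
probabilities instead. The default ROC marker set is the screened variables
with |loading| ≥ 0.29 on V₁ or V₂ — an explicit encoding of "highly
contributing", fully overridable.

## The synthetic cohort

The generator states a world and the tests measure it; its defaults are
never adjusted to make a test pass.

* **Cohort shape.** 36 samples (20 cases / 16 controls), 49386 genes, 28
  immune-cell types with disjoint 30-gene signatures — the shape of the
  blood-expression cohort this analysis style targets. Signature size 30 is
  a typical order for curated immune signatures.
* **Expression.** log2-scale: per-gene baselines ~ N(6, 1.5²), residual
  noise SD 1, and each signature gene shifted by β · (cell abundance), with
  β = 1.0 — a coordinated one-log-unit shift per SD of abundance, the
  strong-marker regime appropriate for cell-proportion-driven whole-blood
  signatures. Latent abundances are standard normal per sample.
* **Cross-block structure.** One shared latent factor z loads equally on
  the CSF triplet (loading c) and on eight linked peripheral channels
  (six cell abundances + TP40 + FP40/FP42; loading d). With
  X_j = c z + √(1−c²) e_j, the best within-block projection has squared
  correlation p c²/(1+(p−1)c²) with z; setting each block's value to ρ and
  solving c² = ρ/(p − ρ(p−1)) plants a population first canonical
  correlation of exactly ρ (closed form asserted at 1e−10). Default
  ρ = 0.794. The rank-1 cross-covariance tests the first canonical
  function, which carries the analysis's headline quantity; later
  population functions are null by construction.
* **Group shifts.** The designated plasma marker FP40/FP42 gets a
  standardized case shift δ = √2·Φ⁻¹(0.709) (population AUC 0.709); the
  Type 1 T helper abundance is reduced in cases by √2·Φ⁻¹(0.703)
  (population AUC 0.703 after orientation). Shifts are added after the
  factor structure, so the planted ρ holds within group and is mildly
  attenuated marginally; recovery experiments therefore use δ = 0 configs.
* **Units.** Standardized channels are mapped affinely to plausible lab
  units (CSF pg/mL-scale locations; plasma ratios around 4.5); affine maps
  change no statistic in the pipeline. FP40 is derived as ratio × FP42 so
  the stored ratio columns are arithmetically consistent.

What a green test does **not** establish: the generator has Gaussian noise,
disjoint signatures, a single shared factor and no batch structure, probe
saturation, missingness or age/sex confounding — so passing tests validate
the statistical machinery, not robustness to real microarray artifacts, and
the simulator makes no attempt to match real marginal distributions.

## Known limitations

* The raw-α screen is reproduced faithfully; with 102 tests it is liberal
  by design, and the BH option changes the selection.
* The Rao F approximation is exact only for min(p_k, q_k) ≤ 2; at
  (p, q, n) = (3, 8, 36) its function-1 null rejection rate is calibrated
  within ±2% (asserted over 1000 replicates).
* Canonical-correlation estimates at n = 36 carry substantial upward bias
  (the worked example's 0.90 vs planted 0.794); parameter-recovery claims
  are made at n = 500.
* Combined-marker AUCs are apparent estimates; with many markers at n = 36
  the logistic fit can separate perfectly, in which case the pipeline
  reports single markers only.
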