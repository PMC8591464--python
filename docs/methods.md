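# Methods

## CPE from DCE-MRI

The study object is a registered multi-timepoint T1-weighted series
(pre-contrast plus post-contrast volumes, by default five series 90 s
apart) with binary breast and fibroglandular masks supplied by upstream
segmentation/registration — those steps are inputs here, not
computations. The delayed-enhancement ratio is computed voxelwise as
`(S_late − S_early)/S_early` with early = the first post-contrast series
(90 s) and late = the last (360 s), both selectable by acquisition time.
Voxels whose early-phase signal falls below `1e-6 ×` the volume maximum
are excluded and counted rather than clamped: unbounded ratios from
near-zero denominators would otherwise dominate the top decile. CPE is
the mean of the top `ceil(0.10 · m)` in-mask valid ratios (minimum one
voxel), after a stable descending sort; ties at the cut carry equal values
so the mean is order-independent. The ratio cancels any global intensity
scale, which the tests assert to 1e-12.

Standardization (mean 0, sample SD 1 with n−1) stores its training
moments, so held-out values can be placed on the reference scale — hazard
ratios for CPE and PC1 are therefore per-SD units.

## Per-gene association and ranking

Counts are normalized to log₂-CPM with pseudocount 0.5
(`log2((c + 0.5)/(L + 1) · 1e6)`), then each gene is regressed on
standardized CPE by simple linear regression, ranked by t = slope/SE
descending with lexicographic gene-id tie-break. The optional
empirical-Bayes mode shrinks per-gene residual variances toward the 10 %
trimmed mean with 4 prior degrees of freedom; it stabilizes rankings at
small n but the plain OLS t is the default because the downstream gene-set
statistics depend on the ranking contract, not a specific shrinkage
recipe. Constant genes get t = 0 and a flag; a perfect fit is capped at
the largest finite float rather than propagating infinities. Pearson
correlations are reported with Fisher-z 95 % intervals,
`tanh(atanh(r) ± 1.96/√(n−3))`.

## Gene set enrichment

The running sum walks the ranked list: a member at rank i adds
`|t_i|^p / Σ_members |t|^p` (weight exponent p = 1 by default; p = 0 gives
the unweighted statistic used by the exact small-sample oracles), a
non-member subtracts `1/(N − k)`. ES is the walk value of maximal
absolute excursion; its 1-based position is "Max ES at", and the
leading-edge fraction counts the members at or before the extremum (at or
after it, for negative ES). Because the walk only rises at member
positions, its extrema lie at a member position or one before it, which
gives an O(k) evaluation used inside the permutation loop; tests verify it
against an explicit O(N) step loop to 1e-12.

The default null permutes the CPE vector and recomputes the entire
ranking per permutation (matching the regression-based ranking design); a
gene-label permutation on the fixed ranking is available as a fast
alternative and is the scheme checked against exhaustive subset
enumeration at N = 20, |S| = 3. NES divides each ES by the mean
same-sign null ES of its own set; null ES values are normalized the same
way and pooled, and the FDR q for a set is the ratio of null to observed
tail fractions on its sign, clipped to [0, 1] — computed separately for
positive and negative NES. Sets are filtered to 5–500 members within the
measured universe by default.

One caution on the reversal symmetry of the walk: reversing the ranking
maps ES → −ES (at p = 0) but moves the extremum to position N − pos, not
N − pos + 1 — a peak just after a member becomes a valley just before the
mirrored member.

## Pathway PC1 and cross-cohort translation

PCA runs on the per-gene z-scaled expression of the set's members
(training mean/SD, n−1); PC1's unit-norm loadings define the pathway
score. The PCA sign is ambiguous, so when a CPE vector is supplied the
loadings are flipped to make cor(PC1, CPE) ≤ 0 — the orientation
convention for a pathway discovered through anti-correlation with CPE —
otherwise the largest-magnitude loading is made positive. Constant genes
are dropped and recorded.

To score a cohort measured on another platform, each shared gene is
linearly mapped to the reference per-gene mean and SD
(`y' = (y − m_t)/s_t · s_ref + m_ref`), after which the frozen centering,
scaling, and loadings apply unchanged; the transform is idempotent and
matches moments to numerical precision. Genes absent from the target are
dropped and the remaining loadings renormalized to unit norm
(zero-imputation was rejected: it biases scores toward 0); a target gene
with zero SD is pinned at the reference mean and flagged. Translation
covers only the model's genes, not the transcriptome.

## Survival models

The Cox partial likelihood uses Breslow tie handling. Firth's penalty
adds `½ log det I(β)` to the log partial likelihood; the modified score
adds `½ tr(I⁻¹ ∂I/∂β_j)` per coordinate, with `∂I/∂β_j` obtained by
central differences (h = 1e-5) of the analytic information matrix —
accurate and cheap at the ≤ 10 covariates these models use. Newton–
Raphson with step-halving guarantees the (penalized) likelihood never
decreases; convergence at max |score| < 1e-6 or |Δ loglik| < 1e-9, 50
iterations maximum. An unpenalized coefficient exceeding 10 in absolute
value marks monotone likelihood (separation) and the fit is flagged, never
silently returned; the Firth fit stays finite in that regime. Wald
intervals from the inverse observed information are the default; profile
penalized-likelihood intervals by bisection on the likelihood-ratio
boundary are available. A warning (not an error) is raised below 5 events
per parameter. Singular designs raise an error naming the collinear
columns.

The study's model layout: age, tumor size, grade as two indicators
(grade 1 reference), and a four-level construct covariate of adjuvant
systemic therapy × any-positive-nodes (reference: no AST, node-negative) —
the two source variables are too correlated to enter separately. Rows
with missing values are dropped (complete-case; no imputation). Three
discovery models are fitted: CPE only, PC1 only, both.

## Synthetic cohorts

The generator's role is to realize the statistical structure the analysis
assumes, with all planted parameters recorded:

* **Imaging.** Ellipsoidal breast (fat, baseline ≈ 400) with an inner
  fibroglandular compartment (baseline ≈ 200) inside a low background;
  fibroglandular voxels follow `S(t) = S0(1 + A_v f(t))` with uptake
  anchors f(90 s) = 0.45 and f(360 s) = 1.0, linearly interpolated — only
  those two values matter for CPE, so the curve between them is free.
  Per-voxel delayed-enhancement ratios are drawn uniform on
  (0, target/0.95), making the expected top-decile mean equal the target,
  and inverted to amplitudes. Recovery error is ~0.002 at 32³.
* **Expression.** Negative-binomial counts; per-gene baseline log-means
  N(log 50, 1), gene-wise dispersions log-normal around 0.15, library-size
  factors log-normal(0, 0.3). Planted genes shift their natural-log mean
  by `gene_effect` (default −0.5) per SD of the regressor; background
  genes are independent of it.
* **Survival.** Weibull proportional hazards (shape 1.2, scale 250
  months), exponential censoring with the rate solved by Brent's method so
  the expected realized censoring fraction hits the target (default 0.85,
  the few-events regime of a screening-detected ER+ cohort).
* **Cohort assembly.** Fast mode draws CPE from 0.1 + 0.9·Beta(2, 3)
  (median ≈ 0.45, spanning ~0.1–1.0, the range this statistic shows in
  breast cohorts); imaging mode synthesizes volumes and recomputes CPE
  through the imaging module — downstream structure is identical by
  construction since both feed the same CPE vector forward. A latent
  pathway activity `ℓ = sign(effect)·ρ·CPE_z + √(1−ρ²)·ε` (ρ = 0.8)
  drives the planted genes and, with CPE, the hazard (defaults:
  log-HR +0.5 on pathway, −0.5 on CPE) — so CPE and pathway are
  correlated but not collinear, allowing the joint-model attenuation
  pattern to emerge. Clinical covariates (age, size, grade, axillary
  load, AST with AST more likely in node-positive patients) use
  distributions typical of an early ER+/HER2− surgical cohort.
  `planted_seed` fixes the planted gene ids so independent cohorts can
  share the pathway for validation scenarios.

What the generator does **not** emulate: breast anatomy beyond nested
ellipsoids, coil/bias/motion artifacts, scanner signal equations,
probe-to-gene mapping of real microarrays, batch effects, or paired
tumor/normal designs. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the assumed model, not
robustness to those real-data complications.

## Pathway selection in the pipeline

Among FDR-passing sets the pipeline selects the largest |NES| (ties:
higher leading edge, then name). Magnitude rather than signed NES is
deliberate: a pathway whose members anti-correlate with CPE is enriched at
the bottom of the ranking with a negative NES and is exactly the discovery
the design targets. If nothing passes, the report records an empty
selection and the survival stages are skipped (CLI exit code 2).

## Problem sizes and numerical choices

The test suite and the acceptance script run at deliberately compact
sizes chosen to keep the statistical checks sharp: oracle equivalence on
32³ volumes and 1000 random rankings; exhaustive null enumeration at
N = 20; planted-screen recovery at 200 subjects × 2000 genes × 50 sets
with 200 permutations × 20 replicates; Firth calibration over 200
replicates at n = 300; validation at n = 1000. Tolerances follow the
quantity: 1e-12 for exact algebraic identities, 1e-10 for linear-algebra
round trips, 1e-5 against independent optimizers, and sampling-error
bands for Monte-Carlo checks. All generators take explicit seeds and are
reproducible bit-for-bit.
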