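# cpegx

A radiogenomic analysis pipeline linking **contralateral parenchymal
enhancement (CPE)** — a quantitative DCE-MRI statistic of the healthy
breast opposite a tumor — to tumor gene-expression pathways and survival
in ER+/HER2− breast cancer, built for imaging–genomics researchers who
want each stage as a tested, reusable library component.

## The analysis

1. **CPE** (`cpegx.imaging`). On registered pre/post-contrast volumes, the
   voxelwise delayed-enhancement ratio is
   `(S_late − S_early) / S_early` (early = 90 s, late = 360 s
   post-contrast), and CPE is the mean of the top 10 % of those ratios
   within the contralateral fibroglandular mask. Dimensionless and
   invariant to global intensity scaling.
2. **Gene ranking** (`cpegx.association`). Counts → log₂-CPM; every gene
   is regressed on standardized CPE and ranked by the *t* statistic of the
   slope (optional empirical-Bayes variance moderation).
3. **GSEA** (`cpegx.gsea`). The weighted running-sum enrichment score
   ES, its normalized form NES = ES / mean(same-sign permutation ES), the
   walk-extremum position ("Max ES at"), the leading-edge fraction, and a
   sign-stratified permutation FDR. The default null permutes the CPE
   vector and re-ranks all genes; sets with FDR < 0.25 are carried
   forward.
4. **Pathway PCA** (`cpegx.pathway`). PCA on the z-scaled expression of
   the selected set; PC1 is the one-number pathway score, sign-oriented to
   correlate negatively with CPE. A frozen model (per-gene reference
   moments + loadings) is carried to an independent cohort by per-gene
   mean/variance moment matching, then projected.
5. **Survival** (`cpegx.survival`). Multivariable Cox proportional-hazards
   models — Firth-penalized (Jeffreys prior, ½ log det I(β)) for the
   few-events discovery cohort, standard for large validation cohorts —
   adjusted for age, tumor size, grade, and a four-level construct of
   adjuvant systemic therapy × nodal positivity; CPE and PC1 enter per SD.
6. **Synthetic cohorts** (`cpegx.synthetic`). Generators for DCE volumes
   with controllable CPE, negative-binomial expression with a planted
   CPE-responsive gene set, and Weibull proportional-hazards survival with
   calibrated censoring — every planted parameter recorded for recovery
   tests.

`cpegx.pipeline` orchestrates the discovery and validation arms from one
config; a thin `cpegx` CLI wraps the same functions.

## Worked example

`python examples/05_full_pipeline.py` simulates a 180-subject discovery
cohort (800 genes, one planted 30-gene pathway anti-correlated with CPE,
survival driven by the latent pathway factor and CPE) plus a 600-subject
validation cohort sharing the pathway, and prints:

```
selected pathway        : PLANTED_PATHWAY
PC1 variance explained  : 0.52
cor(PC1, CPE)           : -0.776
CPE HR per SD (95% CI)  : 0.47 (0.30, 0.74)
validation PC1 HR       : 3.07 (2.58, 3.64)
```

The screen recovers the planted set, its PC1 anti-correlates with CPE as
planted, high CPE is protective (HR < 1 per SD), and the adverse pathway
effect replicates in the independent cohort. The other scripts in
`examples/` demonstrate each stage on its own.

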