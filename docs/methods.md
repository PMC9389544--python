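# Methods

This note documents the statistical models behind `metabosubtype`, the
choices made where the underlying procedures are conventionally
under-specified, and what the synthetic cohorts do and do not emulate.

## Differential metabolite screen

Intensities are modelled per metabolite as log-normal. Fold change is the
ratio of arithmetic group means on the raw intensity scale (the common
metabolomics convention); the test is an empirical-Bayes moderated *t* on
log2 intensities. Per feature *g* the pooled residual variance *s²_g*
(*d_g* = n₁ + n₂ − 2 df) is shrunk towards a prior:

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
    t_g  = log2fc_g / (s̃_g · √(1/n₁ + 1/n₂)),   df = d₀ + d_g,

with the hyperparameters (d₀, s₀²) fitted by the method of moments on
log s²_g (digamma/trigamma moment matching; the trigamma inverse is solved
by Newton iteration). When the observed spread of log-variances does not
exceed its sampling expectation, d₀ = ∞ and the common variance is the
pooled mean; total df is capped at (n features × d_g), matching the standard
hierarchical-model implementation, against which the fit is cross-checked in
the test suite to 1e−8. A plain pooled *t* is available via `d0_override=0`
for sensitivity checks.

Screening thresholds are strict: FDR < 0.05 (BH step-up across all
metabolites jointly) and fold change > 1.2 or < 5/6. A metabolite sitting
exactly on a threshold is not called. Swapping group labels maps fc → 1/fc
and up ↔ down.

Missing-value policy at load time is `reject` by default; `min-impute`
replaces a missing cell with half the metabolite's observed minimum.

## Weighted metabolite co-expression network

All network quantities are computed on log2-transformed, per-metabolite
z-scored profiles. The network is unsigned: adjacency a_ij = |r_ij|^β with
zero diagonal.

* **Soft threshold.** For each candidate power β (1–20), connectivity
  k_i = Σ_j a_ij is binned into 10 equal-width bins and log10(frequency) is
  regressed on log10(mean k). The signed fit is −sign(slope)·R²; the chosen
  power is the smallest with signed R² ≥ 0.85 (configurable). Fewer than 3
  non-empty bins makes the fit undefined (recorded as NA). Mean connectivity
  is strictly decreasing in β whenever some 0 < |r| < 1 exist.
* **Topological overlap.**
  TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij), TOM_ii = 1;
  clustering uses the dissimilarity 1 − TOM.
* **Module detection.** Average-linkage hierarchical clustering with a
  *static absolute height cut* (default 0.92 on the 1 − TOM scale, the
  `cutreeStatic` convention), then discarding clusters below
  `min_module_size` (default 5) as unassigned. The static absolute cut was
  chosen over a quantile-of-merge-heights cut deliberately: under monotone
  average linkage a block's final assembly merge is its largest within-block
  height, so any fixed quantile below (n−k)/(n−1) systematically splits
  tight blocks, while a high quantile glues null data into one cluster. An
  absolute cut exploits the bounded TOM scale instead: correlated blocks
  merge far below 0.92 and unrelated metabolites near 1. It is deterministic
  and order-invariant, unlike the dynamic hybrid cut.
* **Eigenmetabolites.** First principal component of the module's
  standardized profiles, scaled to unit variance and sign-oriented to
  correlate positively with the module mean profile; a singleton module's
  eigenmetabolite is its own standardized profile.
* **Module–trait statistics.** The trait (HER2 IHC 0–3) is treated as
  numeric by default (Pearson; Spearman available by config). Per module:
  r(eigenmetabolite, trait) with its p. Per metabolite: module membership
  MM = |r(metabolite, own eigenmetabolite)| and metabolite trait
  significance MES = |r(metabolite, trait)|. MES is defined per metabolite
  (not per module) because the hub rule is applied per metabolite.
* **Hub selection.** Metabolites of modules with trait p < 0.05 satisfying
  MM > 0.7 and MES > 0.15, both strict; deterministic order (MM descending,
  then id). Raising either threshold can only remove hubs.

The metabolite–metabolite interaction network uses the same standardized
log2 scale; edges require |r| > 0.4 strictly, and isolated nodes are kept in
the GraphML export so hub lists remain complete.

## ssGSEA and two-group GSEA

The per-sample enrichment score follows the integrated-difference statistic.
With genes ordered by decreasing expression (mid-ranks r_j for ties, largest
expression → rank N) and weight exponent α = 0.25:

    ES = Σ_i [P_in^w(i) − P_out(i)],
    P_in^w(i) = Σ_{j≤i, j∈S} r_j^α / Σ_{j∈S} r_j^α,
    P_out(i)  = #{j≤i, j∉S} / (N − |S|).

Scores are rank-based and therefore invariant to any strictly monotone
per-sample transform. With `normalize=True` every score is divided by the
global max − min of the matrix, so the matrix spans exactly one unit. Gene
sets with no overlap are dropped with a warning; a set covering all genes is
rejected (the out-of-set CDF is undefined).

Two-group GSEA ranks genes by the moderated *t* (high vs low), uses the
weighted Kolmogorov–Smirnov running sum with weight |t|¹ and the signed
maximum deviation as ES, and obtains NES and p by sample-label permutation:
NES = ES / mean(|permutation ES of the same sign|) and
p = (1 + #{same-sign perms with |ES*| ≥ |ES|}) / (1 + #same-sign perms), so
p ∈ [1/(n_perm+1), 1]. BH q is computed across sets. Default 1000
permutations; fewer than 100 triggers a warning.

Top/bottom grouping takes the top and bottom ⌊fraction·n⌋ samples (default
30%); ties break by input order (earlier sample wins the high slot).

## Consensus clustering and quadrant subtyping

Monti consensus clustering of pathway genes (items): each of 100 reps draws
⌈0.8·n⌉ items without replacement (and all samples at pFeature = 1), Ward-
clusters them on 1 − Pearson distance at k = 3, and accumulates co-clustering
counts. Consensus M_ij = connected/co-sampled with 0/0 counted as 0 and
flagged; final labels come from Ward clustering of 1 − M. The per-(item, rep)
subsampling draws are keyed by a CRC of the item id, so the consensus matrix
is invariant to item input order and bit-reproducible under a fixed seed.
Ward linkage on a condensed distance matrix uses the squared-update variant
(the `Ward.D2`-style convention).

From each pathway's k clusters the group with the highest mean pairwise
*signed* Pearson correlation is kept (ties: larger cluster, then lowest
label); a signed criterion prevents an anti-correlated cluster from winning.
Each sample's pathway score is the median of the selected genes' z-scored
expression — z-scoring is required for the quadrant boundaries at zero to be
meaningful on an arbitrary log2 scale. The quadrant rule is boundary-
inclusive on the ≤ side: quiescent (AAG ≤ 0, GG ≤ 0), AAG (> 0, ≤ 0),
GG (≤ 0, > 0), mixed (> 0, > 0), giving a partition of all scored samples.

Subtype-specific molecules: a feature is specific to subtype s iff against
each other subtype separately it has log2fc > 0 and BH FDR < 0.05, with the
FDR computed across features within each pairwise comparison (requiring all
three comparisons controls the per-comparison error without pooling
heterogeneous contrasts). Subtypes with < 2 samples are excluded with a
warning. Immune-feature screening is a per-feature Kruskal–Wallis test
across subtypes with strict retention at p < 0.05.

Survival uses the Kaplan–Meier product-limit estimate (censorings tied with
an event time remain at risk at that time) and the k-group log-rank test
with hypergeometric variance (df = k − 1); samples missing time or event for
the chosen endpoint are excluded, and only those. Thorsson-style C1–C6
immune-subtype labels are accepted as an optional clinical column and
cross-tabulated with the metabolic subtypes, not re-derived.

## Synthetic cohorts

`simulate_expression_cohort` draws four subtypes (default proportions ¼
each). Each pathway core gene is

    x_g = noise_sd · (a·on_s + b·f_s + c·ε_gs) + baseline_g,

where `on_s` indicates the pathway being active in sample s (AAG subtype →
AAG core on, GG → GG core, mixed → both, quiescent → neither) and a is the
activity shift (default 1.5 sd). The weights split the between-gene
covariance into an activity component a²·Var(on), a shared latent component
b² = latent_weight·max(0, ρ − a²·Var(on)) (latent_weight default 0.3), and
independent noise c², with the total variance solved so the *marginal*
pairwise core correlation is exactly the configured target ρ (default 0.8).
At zero shift this reduces to the pure latent-factor construction
x = √ρ·f + √(1−ρ)·ε. A pure additive latent construction cannot deliver
both a marginal correlation of 0.8 and clean quadrant recovery at shift 1.5
— the shared latent it requires leaks into the median score and
misclassifies ~6–20% of samples per pathway — which is why most of the
planted correlation is routed through the activity indicator. Survival
times are exponential proportional hazards (baseline median survival two
years; default log hazard ratios: GG +log 2, mixed −log 2, others 0) with
Uniform(0, m) censoring, m solved numerically for the target expected
censoring fraction (default 0.3). Disease-specific events subsample overall
deaths at rate 0.9.

`simulate_metabolome_cohort` (defaults: 112 tumour + 112 healthy samples,
1300 metabolites, matching the profiled cohort scale) draws natural-log
intensities with σ = 0.3; planted fold changes are exact arithmetic-mean
ratios because the group shift is applied on the log scale with equal
variances. Correlated modules share a latent factor (√ρ_w f + √(1−ρ_w) ε);
a trait-linked module's factor is partially aligned with the standardized
HER2 IHC score of the tumour arm so each member correlates with the trait at
the configured level (requires trait_correlation ≤ √ρ_w). HER2 IHC is
ordinal 0–3 with default probabilities (0.40, 0.25, 0.20, 0.15) — a
plausible staining-grade mix for an unselected gastric cancer series —
drawn only for tumour samples. The default planted screen (50 up at FC 1.5,
100 down at FC 2/3) gives the recovery tests meaningful but not saturated
power at n = 112 + 112.

What the generators do *not* emulate: mass-spectrometry batch effects,
intensity-dependent missingness, realistic KEGG pathway topology or gene–
gene regulatory structure, non-proportional hazards, and correlation between
clinical covariates and molecular features beyond the planted HER2 link.
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated generative model, not robustness to those real-data
artefacts.

## Numerical choices and edge cases

* BH correction is order-preserving and idempotent on its own output;
  empty input is an error.
* Rank tests switch from exact to tie-corrected normal approximation at a
  total n of 16 or in the presence of ties; completely tied data yield p = 1
  with a warning rather than NaN.
* Constant (zero-variance) metabolite profiles are excluded from
  correlation-based stages with a warning, using a relative tolerance of
  1e−10 to absorb floating-point noise in exactly-constant rows.
* Eigenmetabolite sign orientation makes module summaries invariant to a
  global sign flip of member profiles.
* Consensus pairs never co-sampled (possible at small reps) get consensus 0
  and are counted in a flag field.
* The scale-free fit is NA (never ±∞) for degenerate connectivity
  distributions; if no power reaches the target the model falls back to the
  best-fitting power with a warning rather than failing.
* All simulation and resampling randomness flows through
  `numpy.random.default_rng` seeded from explicit config fields; identical
  configs give bitwise-identical outputs.

## Problem sizes used in the shipped checks

The recovery checks run at the study design sizes where that matters
statistically — 112 + 112 samples × 1300 metabolites for the screen, 51
tumour samples for the HER2 module power (50 replicates), 400 samples for
subtype recovery, 100 replicate cohorts for log-rank power — and at small
hand-checkable sizes for the exact oracles. These sizes keep the whole suite
in the tens of seconds while leaving the stochastic assertions comfortable
power margins.

## Known limitations

* The 29 immune gene sets used for ssGSEA scoring are user-supplied; the
  bundled fixture sets are synthetic placeholders of matching cardinality,
  not curated signatures.
* KEGG pathway set contents are user-supplied via GMT (licensing); set-name
  auto-detection looks for AAG/ALANINE and GG/GLYCOLYSIS substrings.
* No Cox regression or multivariate survival modelling; the survival module
  compares groups only.
* Module colour naming and figure styling of the upstream WGCNA ecosystem
  are out of scope; modules are numbered by decreasing size.
* Immune-cell deconvolution, drug-sensitivity (IC50) and
  immunotherapy-response predictors are intentionally not implemented; the
  pipeline consumes such annotations as plain clinical columns if present.
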