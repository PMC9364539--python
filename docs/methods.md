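# Methods

This note records the models, estimators, defaults and numerical choices
behind `cchepnet`, and what the synthetic validation does and does not
establish about behavior on real data.

## Study design assumed

The pipeline targets a replicated inbred-panel diet study: S strains (default
22), two diets (HP = high protein, HS = high fat / high sucrose), r
replicates per strain × diet cell (default 3), processed in weekly batches.
Expression is a normalized log2-scale feature × sample matrix (features are
transcript-cluster IDs, possibly several per gene). Upstream probe
summarization and normalization (RMA or similar) are out of scope; a simple
quantile-normalization utility is provided for harmonizing matrices, nothing
more.

## Array QC

Three independent outlier criteria per array:

1. **Distance**: mean Euclidean distance to all other arrays; flagged above
   Q3 + 1.5·IQR of the per-array scores.
2. **Kolmogorov–Smirnov K_a**: sup-distance between the array's intensity
   ECDF and the pooled ECDF over *all* arrays (the array under test is not
   excluded — with ≥ 100 arrays its own contribution is negligible and the
   pooled reference is identical for every array); same boxplot flag rule.
3. **Hoeffding D_a** on MA-plot coordinates A = (x + m)/2, M = x − m against
   the per-gene median array m, using the classical rank statistic with
   midranks for ties; flagged above a fixed threshold (default 0.15).

An array is removed only when **all three** criteria flag it. The boxplot
rule and the fixed Hoeffding threshold are conventions of the array-QC
literature; both are exposed as parameters. Note D_a assumes gene-to-gene
intensity spread dominates array noise (true for log-scale expression data);
on spread-free synthetic noise A and M are intrinsically dependent and D_a
is not a meaningful QC score.

## Expression filter

A feature is kept if its median exceeds the mean of all feature medians, or
if its per-sample expression exceeds that mean-of-medians in strictly more
than 12.5% of samples. The per-sample reading of the second rule is
deliberate: in an eight-founder panel a gene may carry a low/no-expression
allele from one founder, silencing it in ~1/8 of genetic backgrounds; such a
gene still exceeds the threshold in the remaining ~87.5% of samples and must
survive, while a globally silent gene must not. Each gene symbol is then
represented by its single highest-expressed surviving feature ("highest" =
highest mean across samples; median or maximum are selectable; ties break to
the lexicographically smallest feature ID).

The filter is exactly idempotent when the mean-of-medians threshold is held
fixed (it can be passed explicitly). Re-deriving the threshold from already
filtered data shifts it upward, so refiltering can cut borderline genes when
the expressed/unexpressed populations are not well separated; in the bimodal
regime the rule targets, refiltering changes nothing.

## Trait association

Biweight midcorrelation with unscaled MAD (no 1.4826 consistency factor, per
the statistic's definition) and Tukey biweights zeroed outside |u| < 1. A
vector with zero MAD (e.g. majority-constant) falls back to its
mean-centered Pearson form; a vector constant under both schemes is an
error. Missing phenotype values are handled pairwise-complete, and each
gene × trait p-value uses that pair's n. The significance flag is nominal
p < 0.05 (the convention for this screen); a BH-adjusted column is always
emitted alongside so either convention can be applied downstream.

## Differential expression

One shared design — intercept + strain (S−1 treatment columns) + diet (1
column, HP reference) + week — serves both contrasts: diet DEGs from the
moderated t on the diet coefficient, strain DEGs from the moderated F
jointly over the strain block (computed as the RSS difference against the
design without strain columns). The empirical-Bayes step estimates the
variance prior by moment matching on z = log s²: s₀² from mean(z) and d₀
from trigamma⁻¹(var(z) − trigamma(d/2)), solved by Newton iteration. When
the observed spread of z is no larger than its sampling noise the prior df
is infinite and all genes share the pooled variance (handled, not an
error). No intensity-dependent trend is fit on the prior. The implementation
is cross-checked in the test suite against the reference R implementation
(limma) on a shared fixture, to rtol 1e-8 on moderated t and p.

Over-representation of DEG sets in user-supplied GMT collections is a
one-sided hypergeometric tail with BH adjustment; "gene richness" k/K is
reported per set.

## Heritability and variance partitioning

Mean squares are sequential: covariates enter first (diet + week for the
full model; week only for the diet-specific models), the grouping factor
last, so MSB is the covariate-adjusted between-group mean square. The
unbalanced-design effective replicate count n₀ = (N − Σn_s²/N)/(S−1)
appears in the ICC denominators (the pragmatic stand-in for a Satterthwaite
correction; with QC-driven sample loss group sizes are mildly unbalanced).
r_I and g² follow the Festing conventions; estimates can be negative
(within-strain spread exceeding between-strain spread) and are reported as
such. MSW = 0 returns 1.0 rather than an error.

The variance partition fits σ²_strain, σ²_diet, σ²_strain×diet, σ²_resid by
REML. The objective is evaluated on the exact sufficient-statistic
decomposition — within-cell sum of squares plus the cell-mean vector with
covariance σ_s·Z_sZ_sᵀ + σ_d·Z_dZ_dᵀ + σ_i·I + σ_e·diag(1/n_c) — which
equals full-data REML up to a constant but scales with the number of cells
(44) rather than samples (132). Optimization: L-BFGS-B with analytic REML
gradient, box constraints [~0, 10·var(y)], three deterministic starts
(balanced, strain-heavy, residual-heavy), ftol 1e-14. On balanced designs
with interior solutions this reproduces the ANOVA method-of-moments
estimates (verified to 1e-6 in the tests). With one observation per cell the
interaction and residual enter the likelihood only through their sum; the
documented tie-break attributes the ridge to the residual, shrinking the
interaction to zero. POVs divide each component by the sum of all four
(including residual — the percentages in the intended reporting format sum
to well under 100 across strain/diet/interaction, implying the residual is
in the denominator) and are reported ×100.

Diet-specific g² distributions are compared with the two-sided Mann–Whitney
U (normal approximation, tie-corrected) and two-sample KS (asymptotic).
These tests assume independent observations; per-gene estimates within a
planted module share a latent factor, so in heavily coupled simulations the
nominal null calibration degrades (the validation keeps the module share of
the transcriptome realistic, ~15%).

## Co-expression network

Unsigned adjacency |r|^β with Pearson r; soft threshold chosen per the
scale-free criterion: connectivity k binned into 10 equal-count bins,
log10(density) regressed on log10(mean k), signed R² = −sign(slope)·R²,
lowest power with signed R² ≥ 0.9 (argmax fallback with a warning when no
power crosses). Signed TOM as in the README formula; for non-negative
adjacency the signed and unsigned TOM formulas coincide (asserted in code).

Module detection is a dynamic hybrid tree cut implemented from the
algorithm's core ideas; exact agreement with the reference tool is *not* a
contract — planted-module recovery is. On the average-linkage dendrogram of
1 − TOM, a branch becomes a module iff:

* it has ≥ `min_module_size` leaves (default 20);
* its mean internal merge height is ≤ `max_internal_dissim` (default 0.99):
  an absolute ceiling that rejects branches whose topological overlap is at
  the chance level of uncorrelated genes (TOM → 0, dissimilarity → 1, at
  the sample sizes this pipeline targets);
* it contains no well-separated large sub-branch, where "well separated"
  means parent-to-branch height separation ≥ minGap(deepSplit) × dendrogram
  height range, with minGap presets {0.27, 0.2025, 0.135, 0.0675, 0.0375}
  for deepSplit 0–4 (default 2, derived from the reference tool's
  core-scatter presets via minGap = (1 − maxCoreScatter)·3/4).

Branches failing the criteria are recursed into; unassigned genes are grey
(label 0). A PAM-like stage then assigns each grey gene to its nearest
module (smallest average dissimilarity) when that distance is within the
module's radius (largest member-to-module average dissimilarity). Modules
whose eigengenes correlate above 1 − `merge_cut_height` (default 0.15) are
merged iteratively until stable. Eigengenes are unit-norm first left
singular vectors of the samples × member-genes z-score matrix, sign-oriented
to correlate positively with the module's mean standardized expression.
The entire network branch is deterministic: no step draws random numbers.

## Synthetic data generator

Per gene g and sample i:

y = μ_g + a_{g,strain} + β_g·1[HP] + c_{g,strain×diet} + w_{g,week}
\+ λ_g·F_{m(g),i} + ε, with a, c, w, ε centered normal with per-run variances
(defaults σ²_strain = 0.069, σ²_diet = 0.007, σ²_interaction = 0.004,
σ²_batch = 0.005, σ²_resid = 0.143, chosen to place roughly 30% of variance
between strains with diet and interaction an order of magnitude smaller —
the strain-dominant regime this class of study reports; per-gene
component magnitudes are not published, so these are synthetic by
construction). The diet term is a fixed per-gene shift whose magnitude is
drawn β_g ~ N(0, 2σ²_diet): a two-level factor has no meaningful per-gene
"variance", but this scaling makes the implied random-effect variance equal
σ²_diet, so the variance-partitioning estimator has a well-defined truth to
recover. Module factors are unit-variance with a configurable within-strain
variance share (default 0.5) and optional per-module HS mean shifts, making
planted modules genetics- and diet-driven like real co-expression modules;
body fat % is a linear combination of module factors plus a diet effect
(default +2 percentage points on HS) and N(0,1) noise. Founder-null
injection shifts chosen genes down (default 4 log2 units) in a chosen
fraction of strains; duplicate TC-IDs append attenuated copies of chosen
genes under the same symbol. One seeded generator with fixed draw order
makes outputs bit-reproducible.

What the generator does **not** emulate: founder haplotype mosaics and eQTL
architecture, probe-level intensity error, heavy-tailed or heteroskedastic
residuals, correlated phenotype measurement error, and batch structure
confounded with diet or strain. Passing tests therefore establish estimator
correctness and calibration under the generating model, not robustness to
every pathology of real array data.

## Validation scales

The test suite and acceptance script run at desk scale, chosen as the
package's own validation sizes: 100-instance brute-force oracle sweeps for
every numerical primitive; 500 genes × 4 ICC levels for heritability
recovery; 500–1,000 genes for POV recovery; 5,000 genes for null error-rate
checks; 740 genes × 132 samples for planted-module recovery; and a
2,000-gene end-to-end determinism run. The per-gene REML stage is the most
expensive pipeline step, so `PipelineConfig.pov_max_genes` caps it (default
500, deterministic first-N selection; set to `None` for all genes).

## Known limitations

* The dynamic hybrid cut is a faithful re-derivation, not a port; branch
  assignments can differ from the reference tool on borderline topologies.
* Moderated F uses a single shared design for all genes; gene-specific
  missingness in the expression matrix is not supported (the data model
  requires a complete matrix).
* The diet ICC inherits the n₀-based correction rather than a full
  Satterthwaite df computation.
* GWAS-catalog matching is symbol-based (upper-cased, delimiter-split);
  no orthology mapping beyond symbol identity is attempted, and the
  obesity-trait keyword list is run configuration, not a constant.
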