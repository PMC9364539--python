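# cchepnet

Analysis pipeline for hepatic gene expression in replicated inbred mouse
panels (e.g. the Collaborative Cross) under a two-diet challenge — for
quantitative geneticists and nutrigenomics researchers who want to separate
the contributions of genetic background (strain), dietary macronutrient
composition, and their interaction to liver transcript levels, and to relate
co-expressed gene modules to adiposity phenotypes.

The pipeline has two branches operating on the same normalized expression
matrix (features × samples, log2 scale):

* a **single-gene branch**: array QC, expression filtering, robust
  trait–expression correlation, moderated differential expression, and
  per-gene heritability / variance partitioning;
* a **network branch**: weighted co-expression network construction, module
  detection, module eigengenes, and module–trait statistics;

followed by cross-analysis intersections (DEGs × trait-correlated genes ×
GWAS-catalog obesity genes × modules).

## Statistical core

**Robust trait association.** Gene–phenotype association uses the biweight
midcorrelation: with per-vector median *m* and unscaled MAD, observations are
weighted by `w_i = (1 − u_i²)² · 1[|u_i| < 1]`, `u_i = (x_i − m)/(9·MAD)`, and

```
bicor(x, y) = Σ x̃ᵢỹᵢ / (√Σx̃ᵢ² · √Σỹᵢ²),   x̃ᵢ = (xᵢ − m_x)·w_i .
```

Two-sided p-values come from the Student transform
`t = r·√((n−2)/(1−r²))` on the pairwise-complete sample count *n*.

**Moderated differential expression.** Each gene is fit by least squares
against strain + diet + week (HP diet is the reference, so positive diet
coefficients mean higher expression on the high-fat high-sucrose diet).
Residual variances are shrunk toward a scaled-inverse-χ² prior whose
parameters (d₀, s₀²) are estimated by moment matching on log s²ᵍ (trigamma
inversion), giving moderated t (diet coefficient) and moderated F (joint
strain coefficients) on d + d₀ degrees of freedom. Genes with
Benjamini–Hochberg adjusted p < 0.05 are DEGs.

**Broad-sense heritability.** Treating expression as the phenotype, with
covariate-adjusted between/within-strain mean squares MSB, MSW and effective
replicate count `n₀ = (N − Σ n_s²/N)/(S − 1)`:

```
r_I = (MSB − MSW) / (MSB + (n₀ − 1)·MSW)
g²  = (MSB − MSW) / (MSB + (2n₀ − 1)·MSW)
```

g² doubles the additive genetic term in the denominator to account for the
doubling of additive variance under full inbreeding, so g² < r_I for any
heritable gene. A diet ICC uses diet as the grouping factor of the full
model. A random-effects model (strain, diet, strain × diet, residual) fit by
REML partitions each gene's variance into percentages (POV).

**Co-expression network.** Unsigned adjacency `a_ij = |cor(i,j)|^β` with β
chosen as the lowest power whose connectivity distribution fits scale-free
topology at signed R² ≥ 0.9; signed topological overlap
`TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`; average-linkage
clustering of 1 − TOM with a dynamic hybrid branch cut plus PAM-style
reassignment; modules summarized by eigengenes (first PC of standardized
member expression) tested against phenotypes (Spearman), diet
(Wilcoxon rank-sum) and strain (Kruskal–Wallis).

A first-class synthetic-data generator plants all of this structure
(variance components, modules with strain/diet-driven factors, founder-null
alleles, duplicate transcript-cluster IDs) with recorded ground truth, so
every stage is testable without any external download.

## Worked example

```bash
$ cchepnet simulate --seed 7 --n-genes 500 --outdir demo
wrote 500 x 132 dataset to demo

$ cchepnet qc demo/expression.tsv demo/metadata.tsv --out demo/qc.tsv
0 arrays flagged for removal

$ cchepnet de-diet demo/expression.tsv demo/metadata.tsv --out demo/de.tsv
110 diet DEGs at adjusted p < 0.05

$ cchepnet heritability demo/expression.tsv demo/metadata.tsv --out demo/h2.tsv
```

The simulated design is 22 strains × 2 diets × 3 replicates = 132 arrays.
None are QC outliers (the generator plants none by default). 110 of 500
genes respond to diet at BH-adjusted p < 0.05 — the generator draws a fixed
diet shift per gene, and the moderated t picks up the larger ones. The
heritability table gives, for example:

```
    tc_id gene_symbol  r_i_full  g2_full  diet_icc
TC0000001   GENE00001     0.264    0.152     0.019
TC0000002   GENE00002     0.282    0.164     0.020
TC0000003   GENE00003     0.370    0.227     0.172
```

with a median full-model g² of 0.189 and mean r_I of 0.319 — matching the
generator's strain-dominant defaults (strain variance ≈ 0.069 against a
total of ≈ 0.22, i.e. roughly a third of expression variance between
strains, with g² systematically below r_I). Gene 3's elevated diet ICC
(0.172 vs ≈ 0.02) marks it as one of the diet-responsive genes.

The full pipeline (QC → filter → correlate → DE → heritability/POV →
network → intersections) runs with:

```bash
cchepnet pipeline --seed 7 --outdir run1
```

and writes every report as TSV plus a JSON manifest; rerunning with the same
seed and config reproduces every output byte for byte.

## Layout

```
src/cchepnet/
  datamodel.py    data types + TSV/GMT/GWAS-catalog I/O
  simulate.py     synthetic data generator with ground truth
  qc.py           array outlier criteria + expression filter
  association.py  biweight midcorrelation screen
  diffexpr.py     moderated t/F differential expression + enrichment
  heritability.py r_I, g², diet ICC, REML variance partitioning
  network.py      soft threshold, TOM, dynamic hybrid cut, eigengenes
  integrate.py    intersections, module composition, pipeline
  cli.py          `cchepnet` command-line interface
```

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
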