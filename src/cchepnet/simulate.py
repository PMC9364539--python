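"""Synthetic dataset generator with known ground truth.

Emulates the statistical structure of a recombinant-inbred diet study: a panel
of inbred strains (replicated genetic backgrounds) fed one of two diets (HP =
high protein, HS = high fat / high sucrose) in weekly batches, with per-gene
variance components for strain, diet, strain x diet, batch and residual noise,
planted co-expression modules whose latent factors drive an adiposity
phenotype, founder-derived low-expression alleles in a subset of strains, and
genes represented by more than one transcript cluster (TC) ID.

Per-gene model for gene g, sample i::

    y_gi = mu_g + a_g,strain(i) + beta_g * 1[diet(i) = HP]
         + c_g,strain(i),diet(i) + w_g,week(i) + lambda_g * F_m(g),i + eps_gi

with a ~ N(0, sigma2_strain), c ~ N(0, sigma2_interaction),
w ~ N(0, sigma2_batch), eps ~ N(0, sigma2_resid) and F unit-variance module
factors per sample.  A factor can carry strain structure (a configurable
fraction of its variance is shared within strain) and a per-module diet mean
shift, so planted modules behave like genetics- and diet-driven gene
clusters.  The diet term is a fixed per-gene shift; its magnitude is
drawn as beta_g ~ N(0, 2 * sigma2_diet) so that, viewed as a two-level random
effect, the implied diet variance component equals sigma2_diet — this keeps
the generator's ground truth on the same scale the variance-partitioning
estimator reports.

The phenotype is built from module factors:
``body_fat_pct = sum_m gamma_m * F_m,i + delta * 1[diet = HS] + noise``.

All randomness flows through one seeded generator with a fixed draw order, so
a given seed reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, PhenotypeTable

# Default per-gene variance components follow the study regime reported for
# this design: strain variance dominates (~0.069), diet and interaction are
# an order of magnitude smaller (~0.007, ~0.004), and the residual absorbs
# the rest of a total near 0.228 so that strain explains ~30% of variance.
DEFAULT_SIGMA2_STRAIN = 0.069
DEFAULT_SIGMA2_DIET = 0.007
DEFAULT_SIGMA2_INTERACTION = 0.004
DEFAULT_SIGMA2_BATCH = 0.005
DEFAULT_SIGMA2_RESID = 0.143


@dataclass
class SimulationConfig:
    n_strains: int = 22
    n_diets: int = 2
    reps_per_cell: int = 3
    n_weeks: int = 4
    n_genes: int = 2000
    sigma2_strain: float = DEFAULT_SIGMA2_STRAIN
    sigma2_diet: float = DEFAULT_SIGMA2_DIET
    sigma2_interaction: float = DEFAULT_SIGMA2_INTERACTION
    sigma2_batch: float = DEFAULT_SIGMA2_BATCH
    sigma2_resid: float = DEFAULT_SIGMA2_RESID
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    # planted co-expression modules
    module_sizes: tuple[int, ...] = ()
    module_loading: float = 1.0
    #: fraction of each module factor's (unit) variance that is shared within
    #: strain — co-expression modules in inbred panels are largely driven by
    #: genetic background, so member genes remain detectable as strain DEGs
    module_factor_strain_h2: float = 0.5
    #: per-module mean shift of the factor on the HS diet (diet-responsive
    #: modules); defaults to no shift
    module_diet_shifts: tuple[float, ...] = ()
    # phenotype construction
    phenotype_module_loadings: tuple[float, ...] = ()
    phenotype_diet_effect: float = 2.0
    phenotype_noise_sd: float = 1.0
    phenotype_missing_fraction: float = 0.0
    # structural quirks
    founder_null_gene_fraction: float = 0.0
    founder_null_strain_fraction: float = 3 / 22
    founder_null_shift: float = 4.0
    duplicate_tcid_fraction: float = 0.0
    duplicate_attenuation: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("sigma2_strain", "sigma2_diet", "sigma2_interaction",
                     "sigma2_batch", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.reps_per_cell < 1:
            raise ValueError("reps_per_cell must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes sum exceeds n_genes")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if not (0.0 <= self.duplicate_tcid_fraction <= 1.0):
            raise ValueError("duplicate_tcid_fraction must be in [0, 1]")
        if not (0.0 <= self.founder_null_gene_fraction <= 1.0):
            raise ValueError("founder_null_gene_fraction must be in [0, 1]")
        if self.duplicate_tcid_fraction > 0 and self.duplicate_attenuation >= 1:
            raise ValueError("duplicate_attenuation must be < 1")
        if not (0.0 <= self.module_factor_strain_h2 <= 1.0):
            raise ValueError("module_factor_strain_h2 must be in [0, 1]")
        if self.module_diet_shifts and \
                len(self.module_diet_shifts) != len(self.module_sizes):
            raise ValueError("module_diet_shifts length must match module_sizes")


@dataclass
class GroundTruth:
    """Recovery-testing oracle: what the generator actually planted."""

    genes: pd.DataFrame
    # per-gene columns: sigma2_strain, sigma2_diet, sigma2_interaction,
    # sigma2_batch, sigma2_resid, true_icc, module (0 = background),
    # diet_effect, factor_loading, founder_null (bool), founder_null_strains,
    # duplicate_of (original tc_id for attenuated duplicates, else "")
    factors: pd.DataFrame | None  # per-sample module factors (samples x modules)
    phenotype_coefficients: dict = field(default_factory=dict)
    config: SimulationConfig | None = None


def true_icc(sigma2_strain, sigma2_interaction, sigma2_resid):
    """Intraclass correlation implied by the generating components.

    Batch is excluded because the estimators adjust it out as a covariate;
    the diet shift is excluded because it is a fixed effect in those models.
    """
    num = np.asarray(sigma2_strain, dtype=float)
    denom = num + sigma2_interaction + sigma2_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


def _design(config: SimulationConfig, rng: np.random.Generator):
    strains = [f"CC{i + 1:03d}" for i in range(config.n_strains)]
    diets = ["HP", "HS"][: config.n_diets]
    rows = []
    for s in strains:
        for d in diets:
            for r in range(config.reps_per_cell):
                rows.append((s, d, r))
    meta = pd.DataFrame(rows, columns=["strain", "diet", "rep"])
    # weeks assigned cyclically with a seeded shuffle: batches cut across
    # strain/diet cells, as in a rolling phenotyping schedule
    weeks = np.tile(np.arange(config.n_weeks), len(meta) // config.n_weeks + 1)[: len(meta)]
    rng.shuffle(weeks)
    meta["week"] = [f"wk{w + 1}" for w in weeks]
    meta.index = pd.Index(
        [f"S{i + 1:03d}" for i in range(len(meta))], name="sample_id")
    return meta.drop(columns=["rep"])


def simulate_dataset(config: SimulationConfig):
    """Generate (ExpressionDataset, PhenotypeTable, GroundTruth).

    Draw order is fixed: design/weeks, baselines, per-gene diet shifts,
    strain effects, interaction effects, batch effects, module factors,
    residuals, phenotype noise, then structural edits (founder nulls,
    duplicate TC-IDs).  Same seed, same output, bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _design(config, rng)
    n = len(meta)
    G = config.n_genes

    strain_codes = pd.Categorical(meta["strain"]).codes
    diet_is_hp = (meta["diet"] == "HP").to_numpy()
    week_codes = pd.Categorical(meta["week"]).codes
    cell_codes = strain_codes * config.n_diets + (~diet_is_hp).astype(int)

    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
    beta = rng.normal(0.0, np.sqrt(2.0 * config.sigma2_diet), size=G)
    a = rng.normal(0.0, np.sqrt(config.sigma2_strain), size=(G, config.n_strains))
    c = rng.normal(0.0, np.sqrt(config.sigma2_interaction),
                   size=(G, config.n_strains * config.n_diets))
    w = rng.normal(0.0, np.sqrt(config.sigma2_batch), size=(G, config.n_weeks))

    n_modules = len(config.module_sizes)
    if n_modules:
        h2 = config.module_factor_strain_h2
        strain_part = rng.standard_normal(size=(config.n_strains, n_modules))
        indiv_part = rng.standard_normal(size=(n, n_modules))
        factors = (np.sqrt(h2) * strain_part[strain_codes, :]
                   + np.sqrt(1.0 - h2) * indiv_part)
        shifts = list(config.module_diet_shifts) or [0.0] * n_modules
        for m, shift in enumerate(shifts):
            factors[:, m] += shift * (~diet_is_hp)
    else:
        factors = None

    module_label = np.zeros(G, dtype=int)
    loading = np.zeros(G)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        module_label[start:start + size] = m
        loading[start:start + size] = config.module_loading
        start += size

    values = (mu[:, None]
              + a[:, strain_codes]
              + beta[:, None] * diet_is_hp[None, :]
              + c[:, cell_codes]
              + w[:, week_codes])
    if factors is not None:
        for m in range(n_modules):
            sel = module_label == m + 1
            values[sel] += loading[sel, None] * factors[None, :, m].reshape(1, -1)
    values += rng.normal(0.0, np.sqrt(config.sigma2_resid), size=(G, n))

    # phenotypes ---------------------------------------------------------
    gammas = list(config.phenotype_module_loadings)
    gammas += [0.0] * (n_modules - len(gammas))
    body_fat = np.full(n, 25.0)
    for m in range(n_modules):
        body_fat = body_fat + gammas[m] * factors[:, m]
    body_fat = body_fat + config.phenotype_diet_effect * (~diet_is_hp)
    body_fat = body_fat + rng.normal(0.0, config.phenotype_noise_sd, size=n)
    lean = 100.0 - body_fat - np.abs(rng.normal(8.0, 2.0, size=n))
    heat = 0.45 - 0.004 * (body_fat - 25.0) + rng.normal(0.0, 0.02, size=n)
    insulin = np.exp(0.03 * (body_fat - 25.0) + rng.normal(0.0, 0.3, size=n))
    mhs = -0.05 * (body_fat - 25.0) + rng.normal(0.0, 0.5, size=n)
    pheno = pd.DataFrame(
        {
            "body_fat_pct": body_fat,
            "lean_pct": lean,
            "heat_production": heat,
            "insulin": insulin,
            "metabolic_health_score": mhs,
        },
        index=meta.index,
    )
    if config.phenotype_missing_fraction > 0:
        mask = rng.random(pheno.shape) < config.phenotype_missing_fraction
        mask[:, 0] = False  # body fat % is always observed
        pheno = pheno.mask(mask)

    feature_ids = [f"TC{g + 1:07d}" for g in range(G)]
    gene_symbols = [f"GENE{g + 1:05d}" for g in range(G)]
    dataset = ExpressionDataset(
        values=values,
        feature_ids=feature_ids,
        gene_symbols=gene_symbols,
        sample_ids=list(meta.index),
        metadata=meta,
    )

    genes = pd.DataFrame(
        {
            "gene_symbol": gene_symbols,
            "sigma2_strain": config.sigma2_strain,
            "sigma2_diet": config.sigma2_diet,
            "sigma2_interaction": config.sigma2_interaction,
            "sigma2_batch": config.sigma2_batch,
            "sigma2_resid": config.sigma2_resid,
            "true_icc": float(true_icc(config.sigma2_strain,
                                       config.sigma2_interaction,
                                       config.sigma2_resid)),
            "module": module_label,
            "diet_effect": beta,
            "factor_loading": loading,
            "founder_null": False,
            "founder_null_strains": "",
            "duplicate_of": "",
        },
        index=pd.Index(feature_ids, name="tc_id"),
    )
    factor_df = (pd.DataFrame(factors, index=meta.index,
                              columns=[f"M{m + 1}" for m in range(n_modules)])
                 if factors is not None else None)
    truth = GroundTruth(
        genes=genes,
        factors=factor_df,
        phenotype_coefficients={
            "module_loadings": gammas,
            "diet_effect": config.phenotype_diet_effect,
            "noise_sd": config.phenotype_noise_sd,
        },
        config=config,
    )

    if config.founder_null_gene_fraction > 0:
        dataset = inject_founder_nulls(
            dataset, config.founder_null_gene_fraction,
            config.founder_null_strain_fraction, config.founder_null_shift,
            truth=truth, rng=rng)
    if config.duplicate_tcid_fraction > 0:
        dataset = add_duplicate_tcids(
            dataset, config.duplicate_tcid_fraction,
            config.duplicate_attenuation, truth=truth, rng=rng)
    return dataset, PhenotypeTable(pheno), truth


def inject_founder_nulls(dataset: ExpressionDataset, gene_fraction: float,
                         strain_fraction: float, shift: float,
                         truth: GroundTruth | None = None,
                         rng: np.random.Generator | None = None):
    """Shift selected genes down by ``shift`` in a random subset of strains.

    Emulates founder haplotypes carrying low/no-expression alleles: a gene
    is suppressed only in the strains that inherited the null allele, so a
    per-sample expression filter must not discard it.
    """
    if not (0 <= gene_fraction <= 1 and 0 <= strain_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if gene_fraction == 0 or strain_fraction == 0:
        return dataset
    rng = rng if rng is not None else np.random.default_rng(0)
    strains = sorted(set(dataset.metadata["strain"]))
    n_genes = dataset.n_features
    n_pick = int(round(gene_fraction * n_genes))
    n_strain_pick = max(1, int(round(strain_fraction * len(strains))))
    gene_idx = rng.choice(n_genes, size=n_pick, replace=False)
    values = dataset.values.copy()
    strain_arr = dataset.metadata["strain"].to_numpy()
    for g in gene_idx:
        hit = rng.choice(len(strains), size=n_strain_pick, replace=False)
        hit_strains = [strains[i] for i in hit]
        mask = np.isin(strain_arr, hit_strains)
        values[g, mask] -= shift
        if truth is not None:
            tc = dataset.feature_ids[g]
            truth.genes.loc[tc, "founder_null"] = True
            truth.genes.loc[tc, "founder_null_strains"] = ",".join(hit_strains)
    return ExpressionDataset(values, dataset.feature_ids, dataset.gene_symbols,
                             dataset.sample_ids, dataset.metadata.copy())


def add_duplicate_tcids(dataset: ExpressionDataset, fraction: float,
                        attenuation: float,
                        truth: GroundTruth | None = None,
                        rng: np.random.Generator | None = None):
    """Append attenuated duplicate TC-IDs for a random subset of genes.

    The duplicate carries the original signal times ``attenuation`` (< 1)
    plus fresh unit-variance-scaled noise, under the same gene symbol, so
    the best-probe-per-gene selection has something to resolve.
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    if fraction > 0 and attenuation >= 1:
        raise ValueError("attenuation must be < 1")
    if fraction == 0:
        return dataset
    rng = rng if rng is not None else np.random.default_rng(0)
    n_genes = dataset.n_features
    n_pick = int(round(fraction * n_genes))
    gene_idx = np.sort(rng.choice(n_genes, size=n_pick, replace=False))
    dup_values = (attenuation * dataset.values[gene_idx]
                  + rng.normal(0.0, 0.2, size=(n_pick, dataset.n_samples)))
    new_ids = [f"{dataset.feature_ids[g]}d" for g in gene_idx]
    new_syms = [dataset.gene_symbols[g] for g in gene_idx]
    out = ExpressionDataset(
        values=np.vstack([dataset.values, dup_values]),
        feature_ids=dataset.feature_ids + new_ids,
        gene_symbols=dataset.gene_symbols + new_syms,
        sample_ids=dataset.sample_ids,
        metadata=dataset.metadata.copy(),
    )
    if truth is not None:
        add = pd.DataFrame(index=pd.Index(new_ids, name="tc_id"))
        for col in truth.genes.columns:
            add[col] = truth.genes[col].iloc[gene_idx].to_numpy()
        add["duplicate_of"] = [dataset.feature_ids[g] for g in gene_idx]
        truth.genes = pd.concat([truth.genes, add])
    return out


def simulate_scale_free_expression(n_genes: int = 300, n_samples: int = 120,
                                   seed: int = 0) -> np.ndarray:
    """Single-factor data whose co-expression network is approximately
    scale-free under soft thresholding.

    Gene i follows ``x_i = l_i * F + sqrt(1 - l_i^2) * eps`` with loadings
    ``l_i ~ Uniform(0, 1)``; pairwise correlations are then ~``l_i * l_j`` and
    soft-thresholded connectivity ``k_i ~ l_i^beta`` has a power-law density
    ``p(k) ~ k^(1/beta - 1)``.
    """
    rng = np.random.default_rng(seed)
    loadings = rng.uniform(0.0, 1.0, size=n_genes)
    factor = rng.standard_normal(n_samples)
    noise = rng.standard_normal((n_genes, n_samples))
    return (loadings[:, None] * factor[None, :]
            + np.sqrt(1.0 - loadings**2)[:, None] * noise)


def write_ground_truth(truth: GroundTruth, genes_path, factors_path=None,
                       provenance_path=None) -> None:
    """Persist the oracle as TSV plus a provenance header (config + seed)."""
    truth.genes.to_csv(genes_path, sep="\t", float_format="%.17g")
    if factors_path is not None and truth.factors is not None:
        truth.factors.to_csv(factors_path, sep="\t", float_format="%.17g")
    if provenance_path is not None and truth.config is not None:
        import json
        with open(provenance_path, "w", encoding="utf-8") as fh:
            json.dump({"config": asdict(truth.config)}, fh, indent=2, sort_keys=True)
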