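"""Cross-analysis intersections and the end-to-end pipeline.

Combines the per-gene analyses (trait correlation, diet DEGs, strain DEGs),
the GWAS-catalog symbol match, and the network modules into Venn-style
region counts and per-module composition tables, and orchestrates the full
run: QC -> filter -> correlations -> differential expression -> enrichment
-> heritability / variance partitioning -> network -> intersections.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, diffexpr, heritability, network, qc
from .datamodel import (ExpressionDataset, GwasCatalog, PhenotypeTable,
                        load_dataset, read_gene_sets, read_gwas_catalog,
                        write_dataset, FLOAT_FMT)
from .simulate import SimulationConfig, simulate_dataset, write_ground_truth

logger = logging.getLogger(__name__)

#: delimiters that separate multiple symbols inside one MAPPED_GENE field
GWAS_DELIMITERS = (",", ";", " - ", " x ")


def match_gwas_genes(catalog: GwasCatalog, mouse_symbols,
                     delimiters: tuple[str, ...] = GWAS_DELIMITERS):
    """Match catalog MAPPED_GENE fields against mouse symbols.

    Each field is split on the delimiter set, whitespace-stripped and
    upper-cased before intersecting with the (normalized) mouse symbols.
    Returns ``(matched_symbols, provenance)`` where provenance maps each
    catalog row index to the symbols it contributed; unmatchable tokens are
    logged, never silently matched.
    """
    symbols = {str(s).strip().upper() for s in mouse_symbols}
    matched: set[str] = set()
    provenance: dict[int, list[str]] = {}
    unmatched: set[str] = set()
    for i, raw in enumerate(catalog.rows["mapped_gene_field"]):
        tokens = [str(raw)]
        for d in delimiters:
            tokens = [part for t in tokens for part in t.split(d)]
        hits = []
        for t in tokens:
            t = t.strip().upper()
            if not t:
                continue
            if t in symbols:
                hits.append(t)
            else:
                unmatched.add(t)
        if hits:
            matched.update(hits)
            provenance[i] = sorted(set(hits))
    if unmatched:
        logger.info("GWAS matching: %d tokens without a mouse symbol match",
                    len(unmatched))
    return matched, provenance


@dataclass
class IntersectionReport:
    set_names: list[str]
    regions: dict[tuple[bool, ...], set]

    @property
    def region_counts(self) -> dict[tuple[bool, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def count(self, *names: str) -> int:
        """Genes in exactly the named sets and no others."""
        key = tuple(n in names for n in self.set_names)
        return len(self.regions.get(key, set()))

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def intersect_gene_sets(named_sets: dict[str, set]) -> IntersectionReport:
    """All 2^k - 1 disjoint Venn regions for 2-4 named gene sets."""
    if not (2 <= len(named_sets) <= 4):
        raise ValueError("intersect_gene_sets handles 2-4 sets")
    names = list(named_sets)
    sets = [set(named_sets[n]) for n in names]
    universe = set().union(*sets)
    regions: dict[tuple[bool, ...], set] = {}
    for g in universe:
        key = tuple(g in s for s in sets)
        regions.setdefault(key, set()).add(g)
    return IntersectionReport(set_names=names, regions=regions)


def module_composition(module_set, correlation_table, de_diet, de_strain,
                       gwas_set, trait: str = "body_fat_pct") -> pd.DataFrame:
    """Per-module counts and fractions of trait-correlated genes, diet DEGs,
    strain DEGs and GWAS-matched genes, plus a "not assigned" row.

    Trait-correlated means nominal p < 0.05 for the given trait.
    """
    bf_genes = correlation_table.significant_genes(trait)
    diet_genes = de_diet.deg_symbols
    strain_genes = de_strain.deg_symbols
    gwas_set = {str(s).upper() for s in gwas_set}
    rows = []
    mods = module_set.module_ids + [0]
    for m in mods:
        genes = set(module_set.genes_in(m))
        total = len(genes)
        label = f"M{m}" if m else "not assigned"
        if total == 0 and m == 0:
            rows.append({"module": label, "total_genes": 0})
            continue
        row = {"module": label, "total_genes": total}
        for name, ref in (("bf_correlated", bf_genes), ("diet_deg", diet_genes),
                          ("strain_deg", strain_genes), ("gwas", gwas_set)):
            k = len(genes & ref)
            row[f"n_{name}"] = k
            row[f"frac_{name}"] = k / total if total else np.nan
        # the three-way DEG/BF%/GWAS breakdown
        core = genes & bf_genes & gwas_set
        row["n_diet_only_core"] = len(core & (diet_genes - strain_genes))
        row["n_strain_only_core"] = len(core & (strain_genes - diet_genes))
        row["n_both_core"] = len(core & diet_genes & strain_genes)
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    outdir: str = "cchepnet_run"
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    expression_path: str | None = None
    metadata_path: str | None = None
    phenotype_path: str | None = None
    gene_sets_path: str | None = None
    gwas_catalog_path: str | None = None
    gwas_trait_keywords: tuple[str, ...] = ("obes", "body mass", "body fat",
                                            "waist", "adipos", "weight")
    hoeffding_threshold: float = 0.15
    median_fraction: float = 0.125
    network: network.NetworkConfig = field(default_factory=network.NetworkConfig)
    #: cap on genes run through per-gene REML variance partitioning, the
    #: pipeline's most expensive stage; the cap takes the first N filtered
    #: genes (deterministic).  None = all genes.
    pov_max_genes: int | None = 500

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)
        payload = {k: v for k, v in self.__dict__.items() if k != "outdir"}
        blob = json.dumps(payload, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write every report as TSV.

    Deterministic: rerunning with the same config (and seed) reproduces every
    output byte-for-byte.  Stage timings go to a separate ``timings.log``
    that is outside the determinism contract.  Any stage failure raises with
    the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: list[tuple[str, float]] = []

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings.append((name, time.perf_counter() - self.t0))
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}"
                                       ) from exc
        return _Stage()

    def save(df: pd.DataFrame, name: str, index=True):
        df.to_csv(outdir / name, sep="\t", float_format=FLOAT_FMT, index=index,
                  na_rep="NA")

    truth = None
    with stage("load"):
        if config.simulate:
            sim = config.sim
            sim.seed = config.seed
            dataset, phenotypes, truth = simulate_dataset(sim)
            write_dataset(dataset, outdir / "expression.tsv",
                          outdir / "metadata.tsv", phenotypes,
                          outdir / "phenotypes.tsv")
            write_ground_truth(truth, outdir / "ground_truth_genes.tsv",
                               outdir / "ground_truth_factors.tsv",
                               outdir / "provenance.json")
        else:
            if not (config.expression_path and config.metadata_path):
                raise ValueError("expression/metadata paths required unless "
                                 "simulate is set")
            dataset, phenotypes = load_dataset(
                config.expression_path, config.metadata_path,
                config.phenotype_path)
            if phenotypes is None:
                raise ValueError("phenotype table required")

    with stage("qc"):
        qc_report = qc.compute_qc(dataset, config.hoeffding_threshold)
        dataset, _ = qc.remove_outlier_arrays(dataset, qc_report)
        save(qc_report.samples, "qc_report.tsv")

    with stage("filter"):
        dataset, filt = qc.filter_tcids(dataset, config.median_fraction)
        save(filt.features, "filter_report.tsv")

    with stage("correlate"):
        corr = association.correlate_expression_with_traits(dataset, phenotypes)
        save(corr.table, "trait_correlations.tsv")

    with stage("differential_expression"):
        design = diffexpr.build_design(dataset)
        de_diet = diffexpr.call_diet_degs(dataset, design)
        de_strain = diffexpr.call_strain_degs(dataset, design)
        save(de_diet.table, "de_diet.tsv")
        save(de_strain.table, "de_strain.tsv")

    gene_sets = None
    if config.gene_sets_path:
        with stage("enrichment"):
            gene_sets = read_gene_sets(config.gene_sets_path)
            universe = set(dataset.gene_symbols)
            enr_diet = diffexpr.overrepresentation_test(
                de_diet.deg_symbols & universe, universe, dict(gene_sets.items()))
            enr_strain = diffexpr.overrepresentation_test(
                de_strain.deg_symbols & universe, universe, dict(gene_sets.items()))
            save(enr_diet, "enrichment_diet.tsv")
            save(enr_strain, "enrichment_strain.tsv")

    with stage("heritability"):
        herit = heritability.heritability_all(dataset)
        save(herit.table, "heritability.tsv")
        groups = {"diet DEGs": de_diet.deg_symbols,
                  "strain DEGs": de_strain.deg_symbols}
        save(heritability.summarize_heritability(herit, groups),
             "heritability_summary.tsv", index=False)

    with stage("variance_partition"):
        subset = dataset.feature_ids
        if config.pov_max_genes is not None:
            subset = subset[: config.pov_max_genes]
        pov = heritability.partition_variance_all(dataset, subset)
        save(pov, "variance_components.tsv")
        save(heritability.summarize_pov(pov, groups), "pov_summary.tsv",
             index=False)

    with stage("network"):
        net = network.build_network(dataset, config.network, keep_tom=True)
        ms = net.module_set
        save(net.soft_threshold_table, "soft_threshold.tsv")
        save(pd.DataFrame({"tc_id": ms.feature_ids,
                           "gene_symbol": ms.gene_symbols,
                           "module": ms.labels}).set_index("tc_id"),
             "module_labels.tsv")
        save(ms.eigengenes, "module_eigengenes.tsv")
        if len(ms.eigengenes.columns):
            save(network.module_trait_correlation(ms, phenotypes),
                 "me_trait_correlations.tsv", index=False)
            save(network.me_group_tests(ms, dataset.metadata),
                 "me_group_tests.tsv", index=False)
        if net.tom is not None and dataset.n_features <= 1000:
            save(network.export_edge_list(net.tom, dataset.feature_ids),
                 "edge_list.tsv", index=False)

    with stage("integrate"):
        gwas_matched: set[str] = set()
        if config.gwas_catalog_path:
            catalog = read_gwas_catalog(config.gwas_catalog_path,
                                        config.gwas_trait_keywords)
            gwas_matched, _ = match_gwas_genes(catalog, dataset.gene_symbols)
        named = {
            "diet_deg": de_diet.deg_symbols,
            "strain_deg": de_strain.deg_symbols,
            "bf_correlated": corr.significant_genes("body_fat_pct"),
        }
        if gwas_matched:
            named["gwas"] = gwas_matched
        venn = intersect_gene_sets(named)
        venn_rows = [{"region": "|".join(n for n, b in zip(venn.set_names, key)
                                          if b),
                      "count": len(genes)}
                     for key, genes in sorted(venn.regions.items())]
        save(pd.DataFrame(venn_rows), "venn_regions.tsv", index=False)
        save(module_composition(ms, corr, de_diet, de_strain, gwas_matched),
             "module_composition.tsv")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples_after_qc": dataset.n_samples,
        "n_genes_after_filter": dataset.n_features,
        "stages": [name for name, _ in timings],
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "timings.log").write_text(
        "".join(f"{name}\t{dt:.3f}s\n" for name, dt in timings))
    return outdir
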