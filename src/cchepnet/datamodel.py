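"""Shared data model and file I/O for the pipeline.

All stages of the pipeline consume an :class:`ExpressionDataset` (a log2-scale
normalized feature x sample matrix with gene annotation and sample metadata)
and, where phenotypes are involved, a :class:`PhenotypeTable`.  Files are
tab-separated UTF-8 with '.' decimals; the first column is always the row key,
matching GEO series-matrix conventions.  Gene symbols are upper-cased once at
load time so that downstream mouse/human comparisons operate on a single case
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIET_LEVELS = ("HP", "HS")

#: numeric formatting used by every writer; 17 significant digits round-trips
#: IEEE doubles exactly.
FLOAT_FMT = "%.17g"


class DataValidationError(ValueError):
    """Raised when an input file violates a dataset invariant."""


@dataclass
class ExpressionDataset:
    """Feature x sample matrix of normalized log2 expression.

    Parameters
    ----------
    values : ndarray, shape (n_features, n_samples)
    feature_ids : list of str
        Unique transcript-cluster (TC) IDs.
    gene_symbols : list of str
        Per-feature gene symbol, upper-cased; may repeat across features.
    sample_ids : list of str
    metadata : DataFrame indexed by sample_id with columns strain, diet, week.
    """

    values: np.ndarray
    feature_ids: list[str]
    gene_symbols: list[str]
    sample_ids: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(map(str, self.feature_ids))
        self.gene_symbols = [str(s).strip().upper() for s in self.gene_symbols]
        self.sample_ids = list(map(str, self.sample_ids))
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_feat, n_samp = self.values.shape
        if len(self.feature_ids) != n_feat or len(self.gene_symbols) != n_feat:
            raise DataValidationError("feature annotation length mismatch")
        if len(self.sample_ids) != n_samp:
            raise DataValidationError("sample id length mismatch")
        if len(set(self.feature_ids)) != n_feat:
            dups = _dups(self.feature_ids)
            raise DataValidationError(f"duplicate feature id: {sorted(dups)[:5]}")
        if len(set(self.sample_ids)) != n_samp:
            dups = _dups(self.sample_ids)
            raise DataValidationError(f"duplicate sample id: {sorted(dups)[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("expression matrix contains missing/non-finite values")
        if list(self.metadata.index) != self.sample_ids:
            raise DataValidationError("metadata rows not aligned with sample order")
        for col in ("strain", "diet", "week"):
            if col not in self.metadata.columns:
                raise DataValidationError(f"metadata missing column {col!r}")
            if self.metadata[col].isna().any():
                bad = self.metadata.index[self.metadata[col].isna()][0]
                raise DataValidationError(f"sample {bad!r} missing {col}")
        unknown = set(self.metadata["diet"].astype(str)) - set(DIET_LEVELS)
        if unknown:
            raise DataValidationError(f"unknown diet label: {sorted(unknown)}")

    # -- convenience ------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, keep: np.ndarray | list) -> "ExpressionDataset":
        """Return a dataset restricted to the given sample positions/mask."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionDataset(
            values=self.values[:, keep],
            feature_ids=self.feature_ids,
            gene_symbols=self.gene_symbols,
            sample_ids=[self.sample_ids[i] for i in keep],
            metadata=self.metadata.iloc[keep].copy(),
        )

    def subset_features(self, keep: np.ndarray | list) -> "ExpressionDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionDataset(
            values=self.values[keep, :],
            feature_ids=[self.feature_ids[i] for i in keep],
            gene_symbols=[self.gene_symbols[i] for i in keep],
            sample_ids=self.sample_ids,
            metadata=self.metadata.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)
        df.insert(0, "gene_symbol", self.gene_symbols)
        df.index.name = "tc_id"
        return df


@dataclass
class PhenotypeTable:
    """Per-sample numeric traits; NaN marks a missing measurement."""

    data: pd.DataFrame  # index: sample_id, columns: trait names

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def aligned_to(self, sample_ids: list[str]) -> pd.DataFrame:
        """Trait table reindexed to the dataset's sample order (NaN-filled)."""
        return self.data.reindex(sample_ids)


@dataclass
class GeneSetCollection:
    """GMT-style named gene sets with case-normalized member symbols."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def items(self):
        return self.sets.items()


@dataclass
class GwasCatalog:
    """Rows of (trait label, raw MAPPED_GENE field) from a GWAS-catalog TSV.

    The mapped-gene field is kept verbatim; delimiter splitting and symbol
    normalization happen downstream in the integration stage.
    """

    rows: pd.DataFrame  # columns: trait, mapped_gene_field

    def __len__(self) -> int:
        return len(self.rows)


def _dups(items) -> set:
    seen, out = set(), set()
    for x in items:
        if x in seen:
            out.add(x)
        seen.add(x)
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_dataset(expression_path, metadata_path, phenotype_path=None):
    """Load and validate the expression/metadata(/phenotype) TSV trio.

    The expression TSV is keyed by TC-ID with a ``gene_symbol`` column followed
    by one numeric column per sample.  Samples present in the expression matrix
    but absent from metadata are an error; extra metadata rows are dropped with
    a logged warning.

    Returns ``(ExpressionDataset, PhenotypeTable | None)``.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0, dtype={0: str})
    if "gene_symbol" not in expr.columns:
        raise DataValidationError("expression file lacks a gene_symbol column")
    symbols = expr["gene_symbol"].astype(str)
    mat = expr.drop(columns=["gene_symbol"])
    try:
        values = mat.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric expression cell: {exc}") from exc
    if expr.index.duplicated().any():
        raise DataValidationError(
            f"duplicate feature id: {sorted(set(expr.index[expr.index.duplicated()]))[:5]}"
        )

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    missing = [s for s in mat.columns if s not in meta.index]
    if missing:
        raise DataValidationError(f"samples missing from metadata: {missing[:5]}")
    extra = [s for s in meta.index if s not in set(mat.columns)]
    if extra:
        logger.warning("dropping %d metadata rows absent from expression: %s",
                       len(extra), extra[:5])
    meta = meta.loc[list(mat.columns)]

    ds = ExpressionDataset(
        values=values,
        feature_ids=list(expr.index),
        gene_symbols=list(symbols),
        sample_ids=list(mat.columns),
        metadata=meta,
    )

    pheno = None
    if phenotype_path is not None:
        ptab = pd.read_csv(phenotype_path, sep="\t", index_col=0,
                           na_values=["NA", ""])
        unknown = [s for s in ptab.index if s not in set(ds.sample_ids)]
        if unknown:
            raise DataValidationError(
                f"phenotype samples not in expression data: {unknown[:5]}")
        pheno = PhenotypeTable(ptab)
    return ds, pheno


def write_dataset(dataset: ExpressionDataset, expression_path, metadata_path,
                  phenotypes: PhenotypeTable | None = None,
                  phenotype_path=None) -> None:
    """Write the TSV trio with fixed 17-significant-digit numeric formatting."""
    df = dataset.to_frame()
    df.to_csv(expression_path, sep="\t", float_format=FLOAT_FMT)
    meta = dataset.metadata.copy()
    meta.index.name = "sample_id"
    meta.to_csv(metadata_path, sep="\t")
    if phenotypes is not None and phenotype_path is not None:
        out = phenotypes.data.copy()
        out.index.name = "sample_id"
        out.to_csv(phenotype_path, sep="\t", float_format=FLOAT_FMT, na_rep="NA")


def read_gene_sets(gmt_path) -> GeneSetCollection:
    """Parse a GMT file (set_id TAB description TAB member...).

    Member symbols are upper-cased and whitespace-stripped.  A line with fewer
    than three fields is a parse error reported with its line number.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataValidationError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields")
            set_id, desc = fields[0], fields[1]
            members = frozenset(
                s.strip().upper() for s in fields[2:] if s.strip())
            if not members:
                raise DataValidationError(f"GMT line {lineno}: empty member list")
            sets[set_id] = (desc, members)
    return GeneSetCollection(sets)


def read_gwas_catalog(path, trait_keywords, trait_column="DISEASE/TRAIT",
                      gene_column="MAPPED_GENE") -> GwasCatalog:
    """Read a GWAS-catalog-style TSV, keeping rows whose trait label contains
    any of the given keywords (case-insensitive substring match).

    The MAPPED_GENE field is preserved verbatim for downstream delimiter
    parsing; which keywords define "obesity-related" is a run-configuration
    choice, not a constant.
    """
    cat = pd.read_csv(path, sep="\t", dtype=str)
    for col in (trait_column, gene_column):
        if col not in cat.columns:
            raise DataValidationError(f"GWAS catalog lacks required column {col!r}")
    kws = [k.lower() for k in trait_keywords]
    trait = cat[trait_column].fillna("")
    mask = trait.str.lower().apply(lambda t: any(k in t for k in kws))
    rows = pd.DataFrame({
        "trait": trait[mask],
        "mapped_gene_field": cat.loc[mask, gene_column].fillna(""),
    }).reset_index(drop=True)
    return GwasCatalog(rows)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of a matrix to a common distribution.

    Each column's sorted values are replaced by the across-column mean of the
    order statistics (ties receive the mean of their ranks' reference values).
    A convenience for harmonizing externally normalized matrices; full RMA is
    out of scope.
    """
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, axis=0)
    ranks = np.empty_like(order)
    n = values.shape[0]
    np.put_along_axis(ranks, order, np.arange(n)[:, None], axis=0)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = reference[ranks]
    # average reference values over ties within each column
    for j in range(values.shape[1]):
        col = values[:, j]
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=out[:, j])
            counts = np.bincount(inv)
            out[:, j] = (sums / counts)[inv]
    return out
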