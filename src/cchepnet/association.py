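"""Biweight midcorrelation between gene expression and phenotypes.

bicor is a robust correlation: observations are weighted by a Tukey biweight
of their distance from the median in units of 9 * MAD (unscaled median
absolute deviation), so single outliers have bounded influence.  p-values
come from the Student-t transform of the correlation, honoring the actual
pairwise-complete sample count for each gene x trait pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionDataset, PhenotypeTable


class UndefinedCorrelationError(ValueError):
    """A vector is constant under both bicor weighting and Pearson fallback."""


def _biweight_transform(x: np.ndarray):
    """Return the centered, biweight-weighted vector, or None if MAD == 0."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        return None
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two paired vectors.

    Either vector with zero MAD falls back to its Pearson (mean-centered,
    unweighted) form; a vector constant under both schemes raises
    :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("bicor requires paired vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("bicor requires finite input")
    xt = _biweight_transform(x)
    yt = _biweight_transform(y)
    if xt is None:
        xt = x - x.mean()
    if yt is None:
        yt = y - y.mean()
    nx = np.sqrt(np.sum(xt**2))
    ny = np.sqrt(np.sum(yt**2))
    if nx == 0.0 or ny == 0.0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return float(np.clip(np.sum(xt * yt) / (nx * ny), -1.0, 1.0))


def student_p(r: float, n: int) -> float:
    """Two-sided Student correlation p-value on n - 2 df.

    |r| = 1 returns exactly 0 (a perfect correlation, flagged by callers
    rather than raised).
    """
    if n < 3:
        raise ValueError("student_p requires n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class CorrelationTable:
    table: pd.DataFrame
    # columns: gene_symbol, trait, bicor, n, p, p_adj_bh, significant

    def significant_genes(self, trait: str, adjusted: bool = False) -> set[str]:
        t = self.table
        col = "p_adj_bh" if adjusted else "p"
        sel = (t["trait"] == trait) & (t[col] < 0.05) & t["bicor"].notna()
        return set(t.loc[sel, "gene_symbol"])


def correlate_expression_with_traits(dataset: ExpressionDataset,
                                     phenotypes: PhenotypeTable,
                                     traits: list[str] | None = None,
                                     alpha: float = 0.05) -> CorrelationTable:
    """bicor + Student p for every gene x trait pair.

    Missing phenotype values are handled pairwise-complete: each pair uses
    exactly the samples where the trait is observed, and the p-value uses
    that pair's n.  Traits with fewer than 3 complete observations yield NA
    rows with a reason.  The significance flag is nominal p < alpha; a BH
    column is emitted alongside so either convention can be applied.
    """
    traits = traits if traits is not None else phenotypes.traits
    pheno = phenotypes.aligned_to(dataset.sample_ids)
    blocks = []
    for trait in traits:
        y = pheno[trait].to_numpy(dtype=float)
        mask = np.isfinite(y)
        n_obs = int(mask.sum())
        g = dataset.n_features
        if n_obs < 3:
            blocks.append(pd.DataFrame({
                "gene_symbol": dataset.gene_symbols,
                "trait": trait,
                "bicor": np.nan, "n": n_obs, "p": np.nan,
                "note": "fewer than 3 complete observations",
            }, index=dataset.feature_ids))
            continue
        yv = y[mask]
        x = dataset.values[:, mask]
        r = _bicor_rows(x, yv)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n_obs - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n_obs - 2)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        blocks.append(pd.DataFrame({
            "gene_symbol": dataset.gene_symbols,
            "trait": trait,
            "bicor": r, "n": n_obs, "p": p, "note": "",
        }, index=dataset.feature_ids))
    out = pd.concat(blocks)
    out.index.name = "tc_id"
    padj = np.full(len(out), np.nan)
    ok = out["p"].notna().to_numpy()
    if ok.any():
        padj[ok] = multipletests(out["p"].to_numpy()[ok], method="fdr_bh")[1]
    out["p_adj_bh"] = padj
    out["significant"] = out["p"] < alpha
    return CorrelationTable(out)


def _bicor_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise bicor of a matrix against one vector (vectorized)."""
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    safe_mad = np.where(mad == 0.0, 1.0, mad)
    u = (x - med) / (9.0 * safe_mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = np.where(mad == 0.0, x - x.mean(axis=1, keepdims=True), (x - med) * w)

    yt = _biweight_transform(y)
    if yt is None:
        yt = y - y.mean()

    num = xt @ yt
    den = np.sqrt(np.sum(xt**2, axis=1)) * np.sqrt(np.sum(yt**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r = np.where(den == 0.0, np.nan, r)
    return np.clip(r, -1.0, 1.0)
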