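"""Per-gene linear models with empirical-Bayes variance moderation.

Every gene is fit by least squares against a shared design (strain + diet +
week, treatment-coded), residual variances are shrunk toward a common prior
estimated by moment-matching on log residual variances (the moderated-t /
moderated-F approach of microarray linear modeling), and genes are called
differentially expressed at a Benjamini-Hochberg adjusted p < 0.05.

Sign convention: HP is the reference diet level, so a positive diet
coefficient means higher expression on the HS diet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionDataset


@dataclass
class DesignSpec:
    """Design matrix plus bookkeeping for which columns belong to which factor."""

    matrix: np.ndarray
    columns: list[str]
    blocks: dict[str, list[int]]  # factor name -> column indices
    sample_ids: list[str]


def build_design(dataset: ExpressionDataset, strain: bool = True,
                 diet: bool = True, week: bool = True) -> DesignSpec:
    """Intercept + treatment-coded strain, diet (HP reference) and week."""
    meta = dataset.metadata
    cols = [np.ones(dataset.n_samples)]
    names = ["(Intercept)"]
    blocks: dict[str, list[int]] = {}

    def add_factor(name: str, series: pd.Series, levels: list[str]):
        idx = []
        for lev in levels[1:]:
            idx.append(len(names))
            cols.append((series == lev).to_numpy(dtype=float))
            names.append(f"{name}{lev}")
        blocks[name] = idx

    if strain:
        levels = sorted(set(meta["strain"]))
        if len(levels) < 2:
            raise ValueError("strain factor requires >= 2 strains")
        add_factor("strain", meta["strain"], levels)
    if diet:
        levels = [l for l in ("HP", "HS") if (meta["diet"] == l).any()]
        if len(levels) < 2:
            raise ValueError("both diet levels must be present")
        add_factor("diet", meta["diet"], levels)
    if week:
        levels = sorted(set(meta["week"]))
        if len(levels) >= 2:
            add_factor("week", meta["week"], levels)
        else:
            blocks["week"] = []
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignSpec(X, names, blocks, list(dataset.sample_ids))


@dataclass
class GeneFits:
    coefficients: np.ndarray      # genes x p
    stdev_unscaled: np.ndarray    # p (sqrt of diag (X'X)^-1)
    sigma2: np.ndarray            # genes, residual variance s^2_g
    rss: np.ndarray               # genes
    df_resid: int
    design: DesignSpec


def fit_gene_models(dataset: ExpressionDataset, design: DesignSpec) -> GeneFits:
    """Ordinary least squares for every gene against the shared design."""
    X = design.matrix
    n, p = X.shape
    if n <= p:
        raise ValueError("no residual degrees of freedom (n <= rank)")
    if design.sample_ids != dataset.sample_ids:
        raise ValueError("design rows not aligned with dataset samples")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = dataset.values @ (xtx_inv @ X.T).T
    fitted = beta @ X.T
    resid = dataset.values - fitted
    rss = np.sum(resid**2, axis=1)
    df = n - p
    return GeneFits(
        coefficients=beta,
        stdev_unscaled=np.sqrt(np.diag(xtx_inv)),
        sigma2=rss / df,
        rss=rss,
        df_resid=df,
        design=design,
    )


@dataclass
class ModeratedStats:
    df_prior: float         # np.inf allowed
    s2_prior: float
    s2_post: np.ndarray
    df_total: float


def trigamma_inverse(y: float) -> float:
    """Monotone Newton inversion of the trigamma function."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def ebayes_moderate(fits: GeneFits) -> ModeratedStats:
    """Estimate the scaled-inverse-chi-square prior on residual variances.

    Moment matching on z = log s^2: the excess spread of z over the sampling
    noise trigamma(d/2) determines the prior df d0 (trigamma inversion), and
    the mean of z determines the prior variance s0^2.  When the observed
    spread is no larger than the sampling noise the prior df is infinite and
    every gene shares the pooled variance.
    """
    s2 = fits.sigma2
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 genes with positive residual variance")
    d = float(fits.df_resid)
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    if np.isfinite(d0):
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d + d0
    else:
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    return ModeratedStats(df_prior=d0, s2_prior=s02, s2_post=s2_post,
                          df_total=df_total)


@dataclass
class DEResult:
    table: pd.DataFrame
    # columns: gene_symbol, coef (or f-columns), stat, p, p_adj_bh, deg
    df_prior: float
    s2_prior: float
    contrast: str

    @property
    def deg_symbols(self) -> set[str]:
        return set(self.table.loc[self.table["deg"], "gene_symbol"])


def _t_pvalue(t: np.ndarray, df: float) -> np.ndarray:
    if np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df=df)


def _f_pvalue(f: np.ndarray, df1: int, df2: float) -> np.ndarray:
    if np.isinf(df2):
        return stats.chi2.sf(f * df1, df=df1)
    return stats.f.sf(f, dfn=df1, dfd=df2)


def call_diet_degs(dataset: ExpressionDataset, design: DesignSpec | None = None,
                   alpha: float = 0.05) -> DEResult:
    """Moderated t on the diet coefficient, BH across genes, flag at
    adjusted p < alpha.  Positive coefficients mean higher on HS."""
    design = design if design is not None else build_design(dataset)
    if not design.blocks.get("diet"):
        raise ValueError("design lacks a diet column")
    fits = fit_gene_models(dataset, design)
    mod = ebayes_moderate(fits)
    j = design.blocks["diet"][0]
    coef = fits.coefficients[:, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (fits.stdev_unscaled[j] * np.sqrt(mod.s2_post))
    p = _t_pvalue(t, mod.df_total)
    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene_symbol": dataset.gene_symbols,
            "coef_diet_HS": coef,
            "t": t,
            "p": p,
            "p_adj_bh": padj,
            "deg": padj < alpha,
        },
        index=pd.Index(dataset.feature_ids, name="tc_id"),
    )
    return DEResult(table, mod.df_prior, mod.s2_prior, contrast="diet HS vs HP")


def call_strain_degs(dataset: ExpressionDataset, design: DesignSpec | None = None,
                     alpha: float = 0.05) -> DEResult:
    """Moderated F jointly over the strain coefficients."""
    design = design if design is not None else build_design(dataset)
    idx = design.blocks.get("strain")
    if not idx:
        raise ValueError("design lacks strain columns")
    counts = dataset.metadata["strain"].value_counts()
    if (counts < 1).any() or len(counts) < 2:
        raise ValueError("every strain needs >= 1 sample and >= 2 strains")
    fits = fit_gene_models(dataset, design)
    mod = ebayes_moderate(fits)
    keep = [i for i in range(design.matrix.shape[1]) if i not in set(idx)]
    reduced = DesignSpec(design.matrix[:, keep],
                         [design.columns[i] for i in keep],
                         {}, design.sample_ids)
    fits_red = fit_gene_models(dataset, reduced)
    r = len(idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((fits_red.rss - fits.rss) / r) / mod.s2_post
    f = np.clip(f, 0.0, None)
    p = _f_pvalue(f, r, mod.df_total)
    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene_symbol": dataset.gene_symbols,
            "f": f,
            "p": p,
            "p_adj_bh": padj,
            "deg": padj < alpha,
        },
        index=pd.Index(dataset.feature_ids, name="tc_id"),
    )
    return DEResult(table, mod.df_prior, mod.s2_prior, contrast="strain (joint F)")


def overrepresentation_test(deg_symbols, universe_symbols, gene_sets,
                            alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of DEGs in each gene set.

    For each set: overlap k among the n DEGs, set size K within the universe
    of N genes; p = P(X >= k) for X ~ Hypergeometric(N, K, n).  "Gene
    richness" k / K is reported alongside a BH-adjusted column.
    """
    universe = {str(s).upper() for s in universe_symbols}
    degs = {str(s).upper() for s in deg_symbols}
    if not universe:
        raise ValueError("empty universe")
    if not degs <= universe:
        raise ValueError("deg symbols must be a subset of the universe")
    n_univ, n_deg = len(universe), len(degs)
    rows = []
    for set_id, (desc, members) in gene_sets.items():
        in_univ = {str(s).upper() for s in members} & universe
        K = len(in_univ)
        k = len(in_univ & degs)
        if K == 0:
            p = 1.0
        elif k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, n_univ, K, n_deg))
        rows.append((set_id, desc, k, K, (k / K) if K else np.nan, p))
    out = pd.DataFrame(rows, columns=["set_id", "description", "k", "K",
                                      "richness", "p"]).set_index("set_id")
    out["p_adj_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] \
        if len(out) else np.nan
    out["enriched"] = out["p_adj_bh"] < alpha
    return out
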