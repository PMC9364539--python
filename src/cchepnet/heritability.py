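"""Broad-sense heritability and variance partitioning of expression levels.

Treating each gene's expression as a phenotype measured on replicated inbred
strains, broad-sense heritability is estimated from between- and within-strain
mean squares (MSB, MSW) of covariate-adjusted linear models:

    r_I = (MSB - MSW) / (MSB + (n0 - 1) MSW)        intraclass correlation
    g^2 = (MSB - MSW) / (MSB + (2 n0 - 1) MSW)      coefficient of genetic
                                                    determination

where n0 = (N - sum_s n_s^2 / N) / (S - 1) is the effective replicate count
for unbalanced strain sizes.  g^2 doubles the additive genetic term in the
denominator to account for the doubling of additive variance under full
inbreeding, so g^2 < r_I whenever MSB > MSW.  Negative estimates are legal
(within-strain spread exceeding between-strain spread).

Three models are fit per gene: a "full" additive model (strain, diet, week,
both diets pooled) and diet-specific HP / HS models (strain, week).  A diet
intraclass correlation uses diet as the grouping factor of the full model.

Variance partitioning fits a random-effects model (strain, diet,
strain x diet, residual) by REML and reports each component as a percentage
of their sum (POV).  The REML objective is evaluated on the exact cell-mean /
within-cell decomposition, which is equivalent to full-data REML but scales
with the number of strain x diet cells rather than samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import ExpressionDataset


# ---------------------------------------------------------------------------
# mean squares and ICC-style estimators
# ---------------------------------------------------------------------------

def effective_replicates(group_sizes) -> float:
    """Satterthwaite-style effective replicate count n0 for unbalanced groups."""
    n_s = np.asarray(group_sizes, dtype=float)
    N = n_s.sum()
    S = n_s.size
    if S < 2:
        raise ValueError("need >= 2 groups")
    return float((N - np.sum(n_s**2) / N) / (S - 1))


def _residual_maker(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return np.eye(X.shape[0]) - Q @ Q.T


def _dummies(series: pd.Series) -> np.ndarray:
    levels = sorted(set(series))
    return np.column_stack([(series == l).to_numpy(float) for l in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(series), 0))


def strain_mean_squares(y: np.ndarray, meta: pd.DataFrame,
                        covariates: tuple[str, ...] = ("diet", "week")):
    """Sequential (covariates first, strain last) mean squares for one gene.

    Returns (MSB, MSW, n0).  MSB is the covariate-adjusted between-strain
    mean square: (RSS_covariates - RSS_full) / (S - 1).
    """
    y = np.asarray(y, float)
    counts = meta["strain"].value_counts()
    S = len(counts)
    if S < 2:
        raise ValueError("need >= 2 strains")
    if (counts < 1).any():
        raise ValueError("strain with no samples")
    cov_cols = [np.ones((len(meta), 1))]
    for c in covariates:
        cov_cols.append(_dummies(meta[c]))
    X0 = np.column_stack(cov_cols)
    X1 = np.column_stack([X0, _dummies(meta["strain"])])
    if len(y) <= X1.shape[1]:
        raise ValueError("not enough replicates beyond strain count")
    r0 = _residual_maker(X0) @ y
    r1 = _residual_maker(X1) @ y
    rss0, rss1 = float(r0 @ r0), float(r1 @ r1)
    msb = (rss0 - rss1) / (S - 1)
    msw = rss1 / (len(y) - X1.shape[1])
    return msb, msw, effective_replicates(counts.to_numpy())


def intraclass_r(msb: float, msw: float, n0: float) -> float:
    """r_I = (MSB - MSW) / (MSB + (n0 - 1) MSW); 1.0 when MSW == 0."""
    if msw == 0.0:
        return 1.0
    return (msb - msw) / (msb + (n0 - 1.0) * msw)


def genetic_determination_g2(msb: float, msw: float, n0: float) -> float:
    """g^2 = (MSB - MSW) / (MSB + (2 n0 - 1) MSW); 1.0 when MSW == 0."""
    if msw == 0.0:
        return 1.0
    return (msb - msw) / (msb + (2.0 * n0 - 1.0) * msw)


def diet_icc(y: np.ndarray, meta: pd.DataFrame) -> float:
    """Diet intraclass correlation from the full additive model.

    Diet is the grouping factor (entered last after strain and week); the
    within mean square is the full-model residual.
    """
    diets = set(meta["diet"])
    if len(diets) < 2:
        raise ValueError("both diets must be present")
    y = np.asarray(y, float)
    X0 = np.column_stack([np.ones((len(meta), 1)), _dummies(meta["strain"]),
                          _dummies(meta["week"])])
    X1 = np.column_stack([X0, _dummies(meta["diet"])])
    r0 = _residual_maker(X0) @ y
    r1 = _residual_maker(X1) @ y
    rss0, rss1 = float(r0 @ r0), float(r1 @ r1)
    msb = rss0 - rss1  # df = 1 for two diets
    msw = rss1 / (len(y) - X1.shape[1])
    n0 = effective_replicates(meta["diet"].value_counts().to_numpy())
    return intraclass_r(msb, msw, n0)


@dataclass
class HeritabilityTable:
    table: pd.DataFrame
    # per-gene columns: gene_symbol, msb_full, msw_full, n0_full, r_i_full,
    # g2_full, r_i_hp, g2_hp, r_i_hs, g2_hs, msb_diet, diet_icc


def _batch_ms(values: np.ndarray, meta: pd.DataFrame, covariates, group: str):
    """Vectorized sequential mean squares for all genes sharing one design."""
    cov_cols = [np.ones((len(meta), 1))]
    for c in covariates:
        cov_cols.append(_dummies(meta[c]))
    X0 = np.column_stack(cov_cols)
    Xg = _dummies(meta[group])
    X1 = np.column_stack([X0, Xg])
    M0 = _residual_maker(X0)
    M1 = _residual_maker(X1)
    rss0 = np.einsum("gi,gi->g", values @ M0, values)
    rss1 = np.einsum("gi,gi->g", values @ M1, values)
    df_b = Xg.shape[1]
    df_w = len(meta) - X1.shape[1]
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom")
    msb = np.clip(rss0 - rss1, 0.0, None) / df_b
    msw = rss1 / df_w
    n0 = effective_replicates(meta[group].value_counts().to_numpy())
    return msb, msw, n0


def _icc_vec(msb, msw, n0, double=False):
    mult = 2.0 * n0 - 1.0 if double else n0 - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (msb - msw) / (msb + mult * msw)
    return np.where(msw == 0.0, 1.0, out)


def heritability_all(dataset: ExpressionDataset) -> HeritabilityTable:
    """Per-gene r_I and g^2 under the full / HP / HS models plus diet ICC."""
    meta = dataset.metadata
    if len(set(meta["diet"])) < 2:
        raise ValueError("both diets required for the full model")
    msb_f, msw_f, n0_f = _batch_ms(dataset.values, meta, ("diet", "week"), "strain")

    cols = {
        "gene_symbol": dataset.gene_symbols,
        "msb_full": msb_f, "msw_full": msw_f, "n0_full": n0_f,
        "r_i_full": _icc_vec(msb_f, msw_f, n0_f),
        "g2_full": _icc_vec(msb_f, msw_f, n0_f, double=True),
    }
    for diet in ("HP", "HS"):
        sel = (meta["diet"] == diet).to_numpy()
        sub_vals = dataset.values[:, sel]
        sub_meta = meta.loc[sel]
        msb, msw, n0 = _batch_ms(sub_vals, sub_meta, ("week",), "strain")
        key = diet.lower()
        cols[f"r_i_{key}"] = _icc_vec(msb, msw, n0)
        cols[f"g2_{key}"] = _icc_vec(msb, msw, n0, double=True)

    msb_d, msw_d, n0_d = _batch_ms(dataset.values, meta, ("strain", "week"), "diet")
    cols["msb_diet"] = msb_d
    cols["diet_icc"] = _icc_vec(msb_d, msw_d, n0_d)
    table = pd.DataFrame(cols, index=pd.Index(dataset.feature_ids, name="tc_id"))
    return HeritabilityTable(table)


def summarize_heritability(herit: HeritabilityTable,
                           gene_groups: dict[str, set[str]] | None = None
                           ) -> pd.DataFrame:
    """Mean +/- SE, median, quartiles, min, max per estimate and gene group.

    ``gene_groups`` maps a label (e.g. "diet DEGs") to a set of gene symbols;
    "all expressed genes" is always included.
    """
    groups = {"all expressed genes": None}
    if gene_groups:
        groups.update(gene_groups)
    est_cols = ["r_i_full", "r_i_hp", "r_i_hs", "g2_full", "g2_hp", "g2_hs",
                "diet_icc"]
    rows = []
    for label, symbols in groups.items():
        t = herit.table
        if symbols is not None:
            t = t[t["gene_symbol"].isin(symbols)]
        for col in est_cols:
            v = t[col].dropna().to_numpy()
            if v.size == 0:
                continue
            rows.append({
                "estimate": col, "group": label, "n_genes": v.size,
                "mean": v.mean(),
                "se": v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan,
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
                "min": float(v.min()), "max": float(v.max()),
            })
    return pd.DataFrame(rows)


def compare_g2_distributions(g2_hp, g2_hs):
    """Two-sided Mann-Whitney U and two-sample KS on diet-specific g^2.

    Returns ``(U, p_mwu, D, p_ks)``.  The U test uses the normal
    approximation with tie correction; KS uses the asymptotic p-value.
    """
    g2_hp = np.asarray(g2_hp, float)
    g2_hs = np.asarray(g2_hs, float)
    if g2_hp.size < 2 or g2_hs.size < 2:
        raise ValueError("both samples need >= 2 values")
    mwu = stats.mannwhitneyu(g2_hp, g2_hs, alternative="two-sided",
                             method="asymptotic")
    ks = stats.ks_2samp(g2_hp, g2_hs, method="asymp")
    return float(mwu.statistic), float(mwu.pvalue), float(ks.statistic), \
        float(ks.pvalue)


# ---------------------------------------------------------------------------
# REML variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2_strain: float
    sigma2_diet: float
    sigma2_interaction: float
    sigma2_resid: float
    converged: bool

    @property
    def pov(self) -> dict[str, float]:
        total = (self.sigma2_strain + self.sigma2_diet
                 + self.sigma2_interaction + self.sigma2_resid)
        if total <= 0:
            return {k: np.nan for k in ("strain", "diet", "interaction", "resid")}
        return {
            "strain": 100.0 * self.sigma2_strain / total,
            "diet": 100.0 * self.sigma2_diet / total,
            "interaction": 100.0 * self.sigma2_interaction / total,
            "resid": 100.0 * self.sigma2_resid / total,
        }


class _RemlProblem:
    """Cell-mean sufficient statistics for the strain/diet/interaction model.

    Shared across genes: only the per-gene cell means and within-cell SSE
    change, so the indicator Gram matrices are built once.
    """

    def __init__(self, meta: pd.DataFrame):
        cells = list(zip(meta["strain"].astype(str), meta["diet"].astype(str)))
        uniq = sorted(set(cells))
        lookup = {c: i for i, c in enumerate(uniq)}
        self.cell_codes = np.array([lookup[c] for c in cells])
        self.n_cells = len(uniq)
        self.counts = np.bincount(self.cell_codes).astype(float)
        s_codes = pd.factorize(pd.Series([u[0] for u in uniq]), sort=True)[0]
        d_codes = pd.factorize(pd.Series([u[1] for u in uniq]), sort=True)[0]
        if len(set(s_codes)) < 2 or len(set(d_codes)) < 2:
            raise ValueError("need >= 2 strains and both diets")
        self.A_strain = (s_codes[:, None] == s_codes[None, :]).astype(float)
        self.A_diet = (d_codes[:, None] == d_codes[None, :]).astype(float)
        self.D = np.diag(1.0 / self.counts)
        self.N = len(meta)
        self.df_within = self.N - self.n_cells

    def stats_for(self, y: np.ndarray):
        sums = np.bincount(self.cell_codes, weights=y,
                           minlength=self.n_cells)
        ybar = sums / self.counts
        sse = float(np.sum(y**2) - np.sum(self.counts * ybar**2))
        return ybar, max(sse, 0.0)


def _neg_reml(theta, prob: _RemlProblem, ybar, sse):
    ss, sd, si, se = theta
    C = prob.n_cells
    V = (ss * prob.A_strain + sd * prob.A_diet + si * np.eye(C)
         + se * prob.D)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros(4)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    x = np.ones(C)
    Vi_x = np.linalg.solve(V, x)  # via cholesky would be faster; fine at C~44
    xtVix = float(x @ Vi_x)
    beta = float(Vi_x @ ybar) / xtVix
    r = ybar - beta
    q = np.linalg.solve(V, r)
    nll = 0.5 * (logdet + np.log(xtVix) + float(r @ q)
                 + (prob.df_within * np.log(se) if prob.df_within > 0 else 0.0)
                 + sse / se)
    # gradient
    Vi = np.linalg.inv(V)
    P = Vi - np.outer(Vi_x, Vi_x) / xtVix
    grads = []
    for A in (prob.A_strain, prob.A_diet, np.eye(C), prob.D):
        grads.append(0.5 * (np.sum(P * A) - float(q @ A @ q)))
    if prob.df_within > 0:
        grads[3] += 0.5 * (prob.df_within / se - sse / se**2)
    return nll, np.asarray(grads)


def partition_variance(y: np.ndarray, meta: pd.DataFrame,
                       _problem: _RemlProblem | None = None) -> VarianceComponents:
    """REML estimates of strain / diet / strain x diet / residual variances.

    Non-negativity is enforced by box constraints; three deterministic
    restarts guard against local optima near the boundary.  With a single
    observation per cell the interaction is confounded with the residual and
    is shrunk toward zero by the boundary constraint.
    """
    y = np.asarray(y, float)
    prob = _problem if _problem is not None else _RemlProblem(meta)
    ybar, sse = prob.stats_for(y)
    vy = max(float(np.var(y, ddof=1)), 1e-12)
    lo, hi = 1e-10 * vy, 10.0 * vy
    starts = [
        np.array([0.25, 0.25, 0.25, 0.25]) * vy,
        np.array([0.60, 0.05, 0.05, 0.30]) * vy,
        np.array([0.05, 0.05, 0.05, 0.85]) * vy,
    ]
    best = None
    for s0 in starts:
        res = optimize.minimize(
            _neg_reml, s0, args=(prob, ybar, sse), jac=True,
            method="L-BFGS-B", bounds=[(lo, hi)] * 4,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        return VarianceComponents(np.nan, np.nan, np.nan, np.nan, False)
    ss, sd, si, se = [v if v > 2 * lo else 0.0 for v in best.x]
    if prob.df_within == 0:
        # one observation per cell: interaction and residual enter the
        # likelihood only through their sum; attribute the ridge to the
        # residual (conservative tie-break)
        se, si = se + si, 0.0
    return VarianceComponents(ss, sd, si, se, bool(best.success))


def partition_variance_all(dataset: ExpressionDataset,
                           feature_subset: list[str] | None = None
                           ) -> pd.DataFrame:
    """Per-gene variance components and POVs (rows indexed by TC-ID)."""
    prob = _RemlProblem(dataset.metadata)
    if feature_subset is not None:
        pos = {f: i for i, f in enumerate(dataset.feature_ids)}
        idx = [pos[f] for f in feature_subset]
    else:
        idx = range(dataset.n_features)
    rows = []
    for i in idx:
        vc = partition_variance(dataset.values[i], dataset.metadata, prob)
        pov = vc.pov
        rows.append({
            "tc_id": dataset.feature_ids[i],
            "gene_symbol": dataset.gene_symbols[i],
            "sigma2_strain": vc.sigma2_strain,
            "sigma2_diet": vc.sigma2_diet,
            "sigma2_interaction": vc.sigma2_interaction,
            "sigma2_resid": vc.sigma2_resid,
            "pov_strain": pov["strain"],
            "pov_diet": pov["diet"],
            "pov_interaction": pov["interaction"],
            "pov_resid": pov["resid"],
            "converged": vc.converged,
        })
    return pd.DataFrame(rows).set_index("tc_id")


def summarize_pov(pov_table: pd.DataFrame,
                  gene_groups: dict[str, set[str]] | None = None) -> pd.DataFrame:
    """Group-mean variance components and POVs (Table-2-style shape)."""
    groups = {"all expressed genes": None}
    if gene_groups:
        groups.update(gene_groups)
    rows = []
    for label, symbols in groups.items():
        t = pov_table
        if symbols is not None:
            t = t[t["gene_symbol"].isin(symbols)]
        t = t.dropna(subset=["sigma2_strain"])
        if not len(t):
            continue
        rows.append({
            "group": label, "n_genes": len(t),
            "var_strain": t["sigma2_strain"].mean(),
            "pov_strain": t["pov_strain"].mean(),
            "var_diet": t["sigma2_diet"].mean(),
            "pov_diet": t["pov_diet"].mean(),
            "var_interaction": t["sigma2_interaction"].mean(),
            "pov_interaction": t["pov_interaction"].mean(),
        })
    return pd.DataFrame(rows)
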