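"""Array-level quality control and TC-ID expression filtering.

Outlier arrays are flagged by three independent criteria — mean inter-array
distance, Kolmogorov-Smirnov distance between each array's intensity
distribution and the pooled distribution, and Hoeffding's D on MA-plot
coordinates — and an array is removed only when all three agree.

Feature filtering keeps a TC-ID when its median expression exceeds the mean
of all TC-ID medians, or when its per-sample expression exceeds that global
mean-of-medians in more than 12.5% of samples (one of eight founder
haplotypes may carry a low/no-expression allele, so a gene silenced in 1/8
of the genetic backgrounds must survive).  Each gene symbol is then reduced
to its single highest-expressed TC-ID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset


@dataclass
class QCReport:
    samples: pd.DataFrame
    # columns: distance_score, ks_stat, hoeffding_stat,
    #          flag_distance, flag_ks, flag_hoeffding, removed

    @property
    def removed_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["removed"]])


@dataclass
class FilterReport:
    features: pd.DataFrame
    # columns: gene_symbol, median, pass_median_rule, pass_fraction_rule,
    #          selected_for_gene
    mean_of_medians: float


def _boxplot_flags(scores: np.ndarray) -> np.ndarray:
    """Upper-tail boxplot rule: flag values above Q3 + 1.5 * IQR."""
    q1, q3 = np.percentile(scores, [25, 75])
    return scores > q3 + 1.5 * (q3 - q1)


def score_array_distance(dataset: ExpressionDataset) -> np.ndarray:
    """Mean Euclidean distance from each array to every other array."""
    if dataset.n_samples < 3:
        raise ValueError("distance score requires >= 3 samples")
    x = dataset.values
    gram = x.T @ x
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - 2.0 * gram
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.clip(d2, 0.0, None))
    return d.sum(axis=1) / (dataset.n_samples - 1)


def score_array_ks(dataset: ExpressionDataset) -> np.ndarray:
    """K_a: sup-distance between an array's ECDF and the pooled ECDF.

    The pooled distribution includes every array (the array under test is not
    excluded).
    """
    if dataset.n_samples < 2:
        raise ValueError("KS score requires >= 2 samples")
    pooled = np.sort(dataset.values, axis=None)
    n_pool = pooled.size
    n = dataset.values.shape[0]
    out = np.empty(dataset.n_samples)
    for i in range(dataset.n_samples):
        col = np.sort(dataset.values[:, i])
        # evaluate both ECDFs at the array's own jump points and just before
        cdf_pool = np.searchsorted(pooled, col, side="right") / n_pool
        cdf_col_hi = np.arange(1, n + 1) / n
        cdf_col_lo = np.arange(0, n) / n
        pool_lo = np.searchsorted(pooled, col, side="left") / n_pool
        out[i] = max(np.max(np.abs(cdf_col_hi - cdf_pool)),
                     np.max(np.abs(cdf_col_lo - pool_lo)))
    return out


def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D statistic (classical rank form, midranks for ties).

    D = 30 * [(n-2)(n-3) D1 + D2 - 2 (n-2) D3] / [n(n-1)(n-2)(n-3)(n-4)]
    with D1 = sum (Q-1)(Q-2), D2 = sum (R-1)(R-2)(S-1)(S-2),
    D3 = sum (R-2)(S-2)(Q-1); R, S midranks and Q the bivariate rank
    (count of points below-left, ties counted half).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 5 or y.size != n:
        raise ValueError("Hoeffding's D requires paired vectors with n >= 5")
    R = _midrank(x)
    S = _midrank(y)
    # Q via chunked pairwise comparison; phi(a,b) = 1[a<b] + 0.5*1[a==b]
    Q = np.empty(n)
    chunk = max(1, int(4e6) // n)
    for start in range(0, n, chunk):
        xi = x[start:start + chunk, None]
        yi = y[start:start + chunk, None]
        phix = (x[None, :] < xi) + 0.5 * (x[None, :] == xi)
        phiy = (y[None, :] < yi) + 0.5 * (y[None, :] == yi)
        prod = phix * phiy
        # remove the self term (phi = 0.25) and add the conventional +1
        Q[start:start + chunk] = prod.sum(axis=1) - 0.25 + 1.0
    d1 = np.sum((Q - 1.0) * (Q - 2.0))
    d2 = np.sum((R - 1.0) * (R - 2.0) * (S - 1.0) * (S - 2.0))
    d3 = np.sum((R - 2.0) * (S - 2.0) * (Q - 1.0))
    denom = n * (n - 1.0) * (n - 2.0) * (n - 3.0) * (n - 4.0)
    return float(30.0 * ((n - 2.0) * (n - 3.0) * d1 + d2 - 2.0 * (n - 2.0) * d3) / denom)


def _midrank(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def score_array_hoeffding(dataset: ExpressionDataset) -> np.ndarray:
    """D_a between MA-plot coordinates of each array vs the median array.

    For array x and per-gene median m across arrays: A = (x + m) / 2,
    M = x - m.  A well-behaved array has M independent of A (D near 0);
    intensity-dependent bias inflates D.
    """
    if dataset.n_features < 5:
        raise ValueError("Hoeffding QC requires >= 5 features")
    med = np.median(dataset.values, axis=1)
    out = np.empty(dataset.n_samples)
    for i in range(dataset.n_samples):
        x = dataset.values[:, i]
        out[i] = hoeffding_d((x + med) / 2.0, x - med)
    return out


def compute_qc(dataset: ExpressionDataset,
               hoeffding_threshold: float = 0.15) -> QCReport:
    """Score every array by the three criteria and set outlier flags.

    Distance and KS scores use the upper boxplot rule (> Q3 + 1.5 IQR);
    Hoeffding's D uses a fixed threshold (default 0.15).  ``removed`` is true
    only when all three flags agree.
    """
    dist = score_array_distance(dataset)
    ks = score_array_ks(dataset)
    hoef = score_array_hoeffding(dataset)
    f_dist = _boxplot_flags(dist)
    f_ks = _boxplot_flags(ks)
    f_hoef = hoef > hoeffding_threshold
    removed = f_dist & f_ks & f_hoef
    df = pd.DataFrame(
        {
            "distance_score": dist,
            "ks_stat": ks,
            "hoeffding_stat": hoef,
            "flag_distance": f_dist,
            "flag_ks": f_ks,
            "flag_hoeffding": f_hoef,
            "removed": removed,
        },
        index=pd.Index(dataset.sample_ids, name="sample_id"),
    )
    return QCReport(df)


def remove_outlier_arrays(dataset: ExpressionDataset, qc: QCReport):
    """Drop only the samples flagged by all three criteria."""
    if list(qc.samples.index) != dataset.sample_ids:
        raise ValueError("QC report does not match dataset samples")
    keep = ~qc.samples["removed"].to_numpy()
    return dataset.subset_samples(keep), qc


def filter_tcids(dataset: ExpressionDataset,
                 median_fraction: float = 0.125,
                 mean_of_medians: float | None = None):
    """Apply the expression filter and best-probe-per-gene selection.

    A feature passes when its median exceeds the mean of all feature medians
    (rule 1) or its expression exceeds that mean-of-medians in strictly more
    than ``median_fraction`` of samples (rule 2).  Among the surviving
    features of each gene symbol, the one with the highest mean expression is
    selected; ties break to the lexicographically smallest TC-ID.

    ``mean_of_medians`` may be supplied to hold the threshold fixed (e.g. the
    value from a previous run); by default it is recomputed from the data, so
    exact idempotence on re-filtered output is only guaranteed when the
    expressed/unexpressed populations are well separated or the threshold is
    reused explicitly.
    """
    medians = np.median(dataset.values, axis=1)
    mom = float(np.mean(medians)) if mean_of_medians is None \
        else float(mean_of_medians)
    rule1 = medians > mom
    frac_above = np.mean(dataset.values > mom, axis=1)
    rule2 = frac_above > median_fraction
    passed = rule1 | rule2

    means = dataset.values.mean(axis=1)
    selected = np.zeros(dataset.n_features, dtype=bool)
    by_gene: dict[str, int] = {}
    for i in np.flatnonzero(passed):
        sym = dataset.gene_symbols[i]
        best = by_gene.get(sym)
        if best is None:
            by_gene[sym] = i
        elif (means[i], ) > (means[best], ) or (
                means[i] == means[best]
                and dataset.feature_ids[i] < dataset.feature_ids[best]):
            by_gene[sym] = i
    for i in by_gene.values():
        selected[i] = True

    report = FilterReport(
        features=pd.DataFrame(
            {
                "gene_symbol": dataset.gene_symbols,
                "median": medians,
                "pass_median_rule": rule1,
                "pass_fraction_rule": rule2,
                "selected_for_gene": selected,
            },
            index=pd.Index(dataset.feature_ids, name="tc_id"),
        ),
        mean_of_medians=mom,
    )
    return dataset.subset_features(selected), report
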