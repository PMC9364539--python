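"""Weighted co-expression network construction and module analysis.

The network is unsigned: adjacency a_ij = |cor(i, j)|^beta with the soft
threshold beta chosen as the lowest power whose connectivity distribution
fits a scale-free topology with signed R^2 >= 0.9.  Gene-gene similarity is
the signed topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

(for non-negative adjacency the signed and unsigned TOM formulas coincide;
this is asserted).  Modules are branches of the average-linkage dendrogram
of 1 - TOM extracted by a dynamic hybrid cut: a gap-based branch
decomposition followed by a PAM-like reassignment stage, with leftover genes
labeled 0 ("grey").  Each module is summarized by its eigengene — the first
principal component of the member genes' standardized expression — which is
then related to phenotypes (Spearman) and to diet/strain groupings
(Mann-Whitney / Kruskal-Wallis).

The whole pipeline is deterministic: no step draws random numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .datamodel import ExpressionDataset, PhenotypeTable

logger = logging.getLogger(__name__)

#: deepSplit presets: minimum branch-separation gap as a fraction of the
#: dendrogram height range (derived from the reference tool's core-scatter
#: presets via minGap = (1 - maxCoreScatter) * 3/4).
_DEEPSPLIT_MINGAP = {0: 0.27, 1: 0.2025, 2: 0.135, 3: 0.0675, 4: 0.0375}


@dataclass
class NetworkConfig:
    powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.9
    min_module_size: int = 20
    deep_split: int = 2
    merge_cut_height: float = 0.15
    #: absolute ceiling on a module's mean internal dissimilarity; branches
    #: whose topological overlap is at chance level (TOM ~ 0, dissim ~ 1)
    #: are never modules.
    max_internal_dissim: float = 0.99

    def validate(self) -> None:
        if any(p < 1 for p in self.powers):
            raise ValueError("powers must be positive integers")
        if not (0 < self.scale_free_r2_target < 1):
            raise ValueError("scale_free_r2_target must be in (0, 1)")
        if self.deep_split not in _DEEPSPLIT_MINGAP:
            raise ValueError("deep_split must be in 0..4")


@dataclass
class ModuleSet:
    labels: np.ndarray              # per-gene module label, 0 = grey
    feature_ids: list[str]
    gene_symbols: list[str]
    eigengenes: pd.DataFrame        # samples x ME columns ("ME1", ...)
    variance_explained: dict[int, float]

    @property
    def module_ids(self) -> list[int]:
        return sorted(set(self.labels) - {0})

    def module_sizes(self) -> dict[int, int]:
        return {m: int(np.sum(self.labels == m)) for m in self.module_ids}

    def genes_in(self, module: int) -> list[str]:
        return [g for g, l in zip(self.gene_symbols, self.labels) if l == module]


# ---------------------------------------------------------------------------
# soft threshold and adjacency
# ---------------------------------------------------------------------------

def _corr_matrix(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant gene rows have undefined correlations")
    return np.corrcoef(values)


def scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """Signed scale-free fit R^2 and slope for a connectivity vector.

    k is split into equal-count bins; log10 of the empirical density of each
    bin is regressed on log10 of its mean connectivity.  The returned R^2 is
    sign-flipped so that only decreasing p(k) counts as scale-free.
    """
    k = np.asarray(k, float)
    order = np.sort(k)
    edges = np.quantile(order, np.linspace(0, 1, n_bins + 1))
    xs, ys = [], []
    total = k.size
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        if hi <= lo:
            raise ValueError("degenerate connectivity bin (tied k values)")
        in_bin = (k >= lo) & (k < hi) if b < n_bins - 1 else (k >= lo) & (k <= hi)
        cnt = int(in_bin.sum())
        if cnt == 0:
            continue
        density = (cnt / total) / (hi - lo)
        mean_k = float(k[in_bin].mean())
        if mean_k <= 0 or density <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(density))
    if len(xs) < 3:
        raise ValueError("too few usable connectivity bins")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r**2), float(slope)


def pick_soft_threshold(dataset_or_values, config: NetworkConfig | None = None):
    """Scale-free topology table over candidate powers and the chosen beta.

    The chosen beta is the lowest power whose signed R^2 reaches the target;
    if none does, the argmax power is returned with a warning.
    """
    config = config if config is not None else NetworkConfig()
    config.validate()
    values = (dataset_or_values.values
              if isinstance(dataset_or_values, ExpressionDataset)
              else np.asarray(dataset_or_values, float))
    if values.shape[0] < 20:
        raise ValueError("soft-threshold selection requires >= 20 genes")
    corr = np.abs(_corr_matrix(values))
    np.fill_diagonal(corr, 0.0)
    rows = []
    for beta in config.powers:
        a = corr**beta
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k)
        rows.append({"power": beta, "signed_r2": r2, "slope": slope,
                     "mean_k": float(k.mean()), "max_k": float(k.max())})
    table = pd.DataFrame(rows).set_index("power")
    crossing = table.index[table["signed_r2"] >= config.scale_free_r2_target]
    if len(crossing):
        beta = int(crossing[0])
    else:
        beta = int(table["signed_r2"].idxmax())
        logger.warning("no power reached signed R^2 >= %.2f; falling back to "
                       "argmax power %d", config.scale_free_r2_target, beta)
    return table, beta


def adjacency(dataset_or_values, beta: int) -> np.ndarray:
    """Unsigned adjacency a_ij = |r_ij|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    values = (dataset_or_values.values
              if isinstance(dataset_or_values, ExpressionDataset)
              else np.asarray(dataset_or_values, float))
    corr = _corr_matrix(values)
    a = np.abs(corr)**beta
    np.fill_diagonal(a, 1.0)
    return a


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Signed topological overlap matrix from a non-negative adjacency."""
    adj = np.asarray(adj, float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(adj < 0):
        # signed TOM takes |l_ij + a_ij|; for unsigned (non-negative)
        # adjacency the two formulas coincide, which is the supported case
        raise ValueError("adjacency entries must be non-negative")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # l_ij = sum_u a_iu a_uj over u != i, j (diagonal zeroed)
    kmin = np.minimum(k[:, None], k[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# dynamic hybrid tree cut
# ---------------------------------------------------------------------------

def cluster_and_cut(tom: np.ndarray, config: NetworkConfig | None = None
                    ) -> np.ndarray:
    """Average-linkage clustering of 1 - TOM with a dynamic hybrid cut.

    Stage 1 decomposes the dendrogram top-down: a branch becomes a module if
    it is large enough (>= min_module_size), internally tight in absolute
    terms (mean internal merge height <= max_internal_dissim), and contains
    no well-separated large sub-branch (separation >= the deepSplit-dependent
    gap threshold).  Branches failing the criteria are recursed into; leaves
    that never join a module are grey (label 0).

    Stage 2 assigns each grey gene to its nearest module (smallest average
    dissimilarity) when that distance is within the module's radius — the
    largest member-to-module average dissimilarity — mirroring the PAM-like
    stage of the reference algorithm.

    Modules are numbered 1, 2, ... in decreasing size order.
    """
    config = config if config is not None else NetworkConfig()
    config.validate()
    n = tom.shape[0]
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    if n < config.min_module_size:
        logger.warning("fewer genes (%d) than min module size (%d): all grey",
                       n, config.min_module_size)
        return np.zeros(n, dtype=int)

    Z = linkage(squareform(diss, checks=False), method="average")
    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    height_range = max(hmax - hmin, 1e-300)
    min_gap = _DEEPSPLIT_MINGAP[config.deep_split] * height_range

    n_nodes = 2 * n - 1  # leaves 0..n-1, internal n..2n-2
    size = np.ones(n_nodes, dtype=int)
    left = np.full(n_nodes, -1)
    right = np.full(n_nodes, -1)
    node_h = np.zeros(n_nodes)
    sum_h = np.zeros(n_nodes)    # sum of internal merge heights in subtree
    cnt_h = np.zeros(n_nodes)
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        v = n + i
        left[v], right[v] = a, b
        size[v] = size[a] + size[b]
        node_h[v] = Z[i, 2]
        sum_h[v] = sum_h[a] + sum_h[b] + Z[i, 2]
        cnt_h[v] = cnt_h[a] + cnt_h[b] + 1

    # separation of a node = parent's merge height minus its own height;
    # a node is "distinct" if it is large and well separated.
    distinct = np.zeros(n_nodes, dtype=bool)
    has_distinct_desc = np.zeros(n_nodes, dtype=bool)
    for v in range(n, n_nodes):
        for c in (left[v], right[v]):
            sep = node_h[v] - node_h[c]
            if size[c] >= config.min_module_size and sep >= min_gap:
                distinct[c] = True
    for v in range(n, n_nodes):  # children precede parents in index order
        for c in (left[v], right[v]):
            if has_distinct_desc[c] or distinct[c]:
                has_distinct_desc[v] = True

    labels = np.zeros(n, dtype=int)
    next_label = [1]

    def leaves_of(v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u < n:
                out.append(u)
            else:
                stack.extend((left[u], right[u]))
        return out

    def assign(v: int) -> None:
        if size[v] < config.min_module_size:
            return  # grey
        mean_internal = sum_h[v] / cnt_h[v] if cnt_h[v] else 0.0
        composite = has_distinct_desc[v]
        if not composite and mean_internal <= config.max_internal_dissim:
            lab = next_label[0]
            next_label[0] += 1
            for leaf in leaves_of(v):
                labels[leaf] = lab
            return
        if v >= n:
            assign(left[v])
            assign(right[v])

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 2 * n + 100))
    try:
        assign(n_nodes - 1)
    finally:
        sys.setrecursionlimit(old_limit)

    labels = _pam_stage(diss, labels)
    return _relabel_by_size(labels)


def _pam_stage(diss: np.ndarray, labels: np.ndarray) -> np.ndarray:
    mods = sorted(set(labels) - {0})
    if not mods:
        return labels
    grey = np.flatnonzero(labels == 0)
    if grey.size == 0:
        return labels
    out = labels.copy()
    radii = {}
    centroids = {}
    for m in mods:
        idx = np.flatnonzero(labels == m)
        sub = diss[np.ix_(idx, idx)]
        # average dissimilarity of each member to the rest of the module
        member_avg = sub.sum(axis=1) / max(len(idx) - 1, 1)
        radii[m] = float(member_avg.max())
        centroids[m] = idx
    for g in grey:
        best_m, best_d = 0, np.inf
        for m in mods:
            d = float(diss[g, centroids[m]].mean())
            if d < best_d:
                best_m, best_d = m, d
        if best_d < radii[best_m]:
            out[g] = best_m
    return out


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    mods = sorted(set(labels) - {0},
                  key=lambda m: (-int(np.sum(labels == m)), m))
    mapping = {0: 0}
    mapping.update({m: i + 1 for i, m in enumerate(mods)})
    return np.array([mapping[l] for l in labels], dtype=int)


# ---------------------------------------------------------------------------
# eigengenes and module statistics
# ---------------------------------------------------------------------------

def module_eigengenes(dataset: ExpressionDataset, labels: np.ndarray
                      ) -> ModuleSet:
    """First principal component per module on standardized member genes.

    The eigengene is the unit-norm left singular vector of the samples x
    genes z-score matrix, oriented to correlate positively with the module's
    average standardized expression; variance explained is the leading
    squared singular value over the total.
    """
    labels = np.asarray(labels, int)
    mods = sorted(set(labels) - {0})
    if not mods:
        raise ValueError("no non-grey modules")
    me = {}
    varexp = {}
    for m in mods:
        idx = np.flatnonzero(labels == m)
        x = dataset.values[idx]
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        z = ((x - mu) / sd).T  # samples x genes
        if z.shape[1] == 1:
            v = z[:, 0]
            me_vec = v / np.linalg.norm(v)
            varexp[m] = 1.0
        else:
            u, s, _ = np.linalg.svd(z, full_matrices=False)
            me_vec = u[:, 0]
            varexp[m] = float(s[0]**2 / np.sum(s**2))
        avg = z.mean(axis=1)
        if np.dot(me_vec, avg) < 0:
            me_vec = -me_vec
        me[f"ME{m}"] = me_vec
    eig = pd.DataFrame(me, index=pd.Index(dataset.sample_ids, name="sample_id"))
    return ModuleSet(labels=labels, feature_ids=list(dataset.feature_ids),
                     gene_symbols=list(dataset.gene_symbols),
                     eigengenes=eig, variance_explained=varexp)


def merge_close_modules(dataset: ExpressionDataset, labels: np.ndarray,
                        cut_height: float = 0.15) -> np.ndarray:
    """Iteratively merge modules whose eigengenes are highly correlated.

    Eigengene dissimilarity 1 - cor(ME) is clustered (average linkage);
    clusters joined below ``cut_height`` are merged, eigengenes recomputed,
    and the process repeats until no merge occurs.
    """
    labels = np.asarray(labels, int).copy()
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        ms = module_eigengenes(dataset, labels)
        me = ms.eigengenes[[f"ME{m}" for m in mods]].to_numpy().T
        diss = 1.0 - np.corrcoef(me)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        Z = linkage(squareform(diss, checks=False), method="average")
        from scipy.cluster.hierarchy import fcluster
        groups = fcluster(Z, t=cut_height, criterion="distance")
        if len(set(groups)) == len(mods):
            break
        mapping = {}
        for g in sorted(set(groups)):
            members = [mods[i] for i in np.flatnonzero(groups == g)]
            target = min(members)
            for m in members:
                mapping[m] = target
        labels = np.array([mapping.get(l, 0) for l in labels], dtype=int)
    return _relabel_by_size(labels)


def module_trait_correlation(module_set: ModuleSet,
                             phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Spearman rho and p for every eigengene x trait pair
    (pairwise-complete)."""
    pheno = phenotypes.aligned_to(list(module_set.eigengenes.index))
    rows = []
    for me_name in module_set.eigengenes.columns:
        me = module_set.eigengenes[me_name].to_numpy()
        if np.all(me == me[0]):
            raise ValueError(f"constant eigengene {me_name}")
        for trait in pheno.columns:
            y = pheno[trait].to_numpy(float)
            mask = np.isfinite(y)
            if mask.sum() < 3:
                rows.append((me_name, trait, np.nan, np.nan, int(mask.sum())))
                continue
            rho, p = stats.spearmanr(me[mask], y[mask])
            rows.append((me_name, trait, float(rho), float(p), int(mask.sum())))
    return pd.DataFrame(rows, columns=["module", "trait", "rho", "p", "n"])


def me_group_tests(module_set: ModuleSet, metadata: pd.DataFrame) -> pd.DataFrame:
    """Diet (Mann-Whitney / Wilcoxon rank-sum) and strain (Kruskal-Wallis)
    effects on each module eigengene."""
    diets = metadata["diet"].to_numpy()
    strains = metadata["strain"].to_numpy()
    if len(set(diets)) < 2:
        raise ValueError("both diets required")
    if len(set(strains)) < 2:
        raise ValueError(">= 2 strains required")
    rows = []
    for me_name in module_set.eigengenes.columns:
        me = module_set.eigengenes[me_name].to_numpy()
        hp, hs = me[diets == "HP"], me[diets == "HS"]
        if hp.size == 0 or hs.size == 0:
            raise ValueError("a diet group has no observations")
        u = stats.mannwhitneyu(hp, hs, alternative="two-sided")
        groups = [me[strains == s] for s in sorted(set(strains))]
        kw = stats.kruskal(*groups)
        rows.append((me_name, float(u.statistic), float(u.pvalue),
                     float(kw.statistic), float(kw.pvalue)))
    return pd.DataFrame(rows, columns=["module", "mwu_u", "p_diet",
                                       "kruskal_h", "p_strain"])


@dataclass
class NetworkResult:
    config: NetworkConfig
    beta: int
    soft_threshold_table: pd.DataFrame
    module_set: ModuleSet
    tom: np.ndarray | None = field(default=None, repr=False)


def build_network(dataset: ExpressionDataset,
                  config: NetworkConfig | None = None,
                  beta: int | None = None,
                  keep_tom: bool = False) -> NetworkResult:
    """End-to-end network construction: soft threshold, adjacency, TOM,
    dynamic hybrid cut, module merging, eigengenes."""
    config = config if config is not None else NetworkConfig()
    table, chosen = pick_soft_threshold(dataset, config)
    beta = beta if beta is not None else chosen
    adj = adjacency(dataset, beta)
    tom = tom_similarity(adj)
    labels = cluster_and_cut(tom, config)
    if len(set(labels) - {0}) >= 2:
        labels = merge_close_modules(dataset, labels, config.merge_cut_height)
    if set(labels) == {0}:
        module_set = ModuleSet(labels=labels,
                               feature_ids=list(dataset.feature_ids),
                               gene_symbols=list(dataset.gene_symbols),
                               eigengenes=pd.DataFrame(
                                   index=pd.Index(dataset.sample_ids,
                                                  name="sample_id")),
                               variance_explained={})
    else:
        module_set = module_eigengenes(dataset, labels)
    return NetworkResult(config=config, beta=beta, soft_threshold_table=table,
                         module_set=module_set,
                         tom=tom if keep_tom else None)


def export_edge_list(tom: np.ndarray, feature_ids: list[str],
                     threshold: float = 0.1) -> pd.DataFrame:
    """Plain edge-list export (gene1, gene2, TOM weight, above-threshold
    flag) for external visualization tools."""
    n = tom.shape[0]
    iu = np.triu_indices(n, k=1)
    return pd.DataFrame({
        "gene1": [feature_ids[i] for i in iu[0]],
        "gene2": [feature_ids[j] for j in iu[1]],
        "tom": tom[iu],
        "above_threshold": tom[iu] >= threshold,
    })
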