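"""Weighted gene co-expression network analysis core.

Builds an unsigned co-expression network a_ij = |cor(x_i, x_j)|^beta, selects
the soft-threshold power beta by the scale-free topology criterion, converts
adjacency to topological overlap (TOM), detects modules by average-linkage
clustering of 1 - TOM with a deterministic tree cut, summarizes each module by
its eigengene (first principal component of the standardized module
expression) and correlates eigengenes with the binary tumor trait.

The tree cut is intentionally simple and fully deterministic: a static cut
near the top of the dendrogram, refined by recursively splitting any cluster
whose top merge height stands clear of its children's heights by more than a
configurable fraction, followed by a cohesion check (clusters must complete
below ``max_cluster_height`` on the 1 - TOM scale) and a minimum-size filter.
Clusters failing either check are pooled into the reserved "grey" label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from mirtfnet.preprocess import ExpressionProfile

__all__ = [
    "CoexpressionResult",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_trait_stats",
    "select_trait_module",
    "run_coexpression",
]

GREY = "grey"


@dataclass
class CoexpressionResult:
    """Module labels, eigengenes and module-trait statistics for one run."""

    module_labels: pd.Series  # gene -> module id ("grey" = unassigned)
    eigengenes: pd.DataFrame  # module x sample
    module_trait_r: pd.Series
    module_trait_p: pd.Series
    beta_used: int

    def module_members(self, module_id: str) -> list[str]:
        return list(self.module_labels.index[self.module_labels == module_id])


def _abs_correlation(values: np.ndarray, gene_ids) -> np.ndarray:
    sd = values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [gene_ids[i] for i in np.nonzero(sd == 0)[0][:5]]
        raise ValueError(f"zero-variance gene(s): {bad}")
    return np.abs(np.corrcoef(values))


def adjacency(profile: ExpressionProfile, beta: int) -> pd.DataFrame:
    """Unsigned adjacency a_ij = |Pearson cor|^beta with zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    a = _abs_correlation(profile.values.to_numpy(dtype=float), profile.feature_ids) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=profile.feature_ids, columns=profile.feature_ids)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free fit index R^2 x sign(-slope) of log p(k) vs log k.

    Connectivities are discretized into ``n_bins`` equal-width bins; the mean
    connectivity and the occupancy fraction of each non-empty bin enter a
    log10-log10 linear regression.
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, p_k = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0 or members.mean() <= 0:
            continue
        mean_k.append(members.mean())
        p_k.append(members.size / k.size)
    if len(mean_k) < 2:
        raise ValueError("fewer than 2 non-empty connectivity bins; fit undefined")
    fit = stats.linregress(np.log10(mean_k), np.log10(p_k))
    return fit.rvalue**2 * np.sign(-fit.slope)


def pick_soft_threshold(
    profile: ExpressionProfile,
    betas=tuple(range(1, 21)),
    r2_target: float = 0.85,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, int]:
    """Scan candidate powers and choose the soft threshold.

    Returns the per-beta scan table (fit_r2, mean_k, median_k) and the chosen
    beta: the smallest power whose signed fit index reaches ``r2_target``, or
    the argmax of the fit index if none does.
    """
    betas = list(betas)
    if len(betas) < 3:
        raise ValueError("need at least 3 candidate betas")
    values = profile.values.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        warnings.warn("excluding zero-variance genes from soft-threshold scan")
        values = values[sd > 0]
    if values.shape[0] < 20 or values.shape[1] < 4:
        raise ValueError("soft-threshold scan needs >= 20 genes and >= 4 samples")
    cor = np.abs(np.corrcoef(values))
    np.fill_diagonal(cor, 0.0)

    rows = []
    for beta in betas:
        a = cor**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=0)
        try:
            r2 = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2 = np.nan
        rows.append(
            {"beta": beta, "fit_r2": r2, "mean_k": k.mean(), "median_k": np.median(k)}
        )
    scan = pd.DataFrame(rows)

    ok = scan[scan["fit_r2"] >= r2_target]
    if len(ok):
        chosen = int(ok["beta"].iloc[0])
    else:
        chosen = int(scan.loc[scan["fit_r2"].idxmax(), "beta"])
    return scan, chosen


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of an unsigned adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with l_ij the shared
    neighbor sum, TOM_ii = 1. Pairs with a non-positive denominator (mutually
    isolated genes) get overlap 0.
    """
    labels = None
    if isinstance(adj, pd.DataFrame):
        labels = adj.index
        a = adj.to_numpy(dtype=float)
    else:
        a = np.asarray(adj, dtype=float)
    k = a.sum(axis=0)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    bad = denom <= 0
    if bad.any():
        warnings.warn("isolated gene pair(s) with non-positive TOM denominator; set to 0")
        tom[bad] = 0.0
    np.fill_diagonal(tom, 1.0)
    if labels is not None:
        return pd.DataFrame(tom, index=labels, columns=labels)
    return tom


def detect_modules(
    tom: pd.DataFrame | np.ndarray,
    min_module_size: int = 20,
    cut_height_frac: float = 0.995,
    gap_frac: float = 0.10,
    max_cluster_height: float = 0.99,
) -> pd.Series:
    """Assign genes to co-expression modules from a TOM similarity matrix.

    Average-linkage clustering of the dissimilarity 1 - TOM. The tree is
    descended from the root: a node is split whenever it completes above the
    static cut (``cut_height_frac`` x top merge height), above the absolute
    cohesion height ``max_cluster_height`` (on the 1 - TOM scale), or when
    its merge height stands clear of both children's heights by more than
    ``gap_frac`` of its own height. Surviving clusters of at least
    ``min_module_size`` genes become modules; everything else is "grey".

    Module ids are "M1", "M2", ... ordered by decreasing size (ties by first
    member position), so labels are deterministic given the input.
    """
    if isinstance(tom, pd.DataFrame):
        gene_ids = list(tom.index)
        t = tom.to_numpy(dtype=float)
    else:
        t = np.asarray(tom, dtype=float)
        gene_ids = [f"g{i}" for i in range(t.shape[0])]
    n = t.shape[0]
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size; all grey")
        return pd.Series(GREY, index=gene_ids)

    d = 1.0 - t
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = linkage(squareform(d, checks=False), method="average")
    root = to_tree(z)
    cut_height = cut_height_frac * root.dist

    clusters: list[tuple[list[int], float]] = []  # (leaf ids, completion height)

    def recurse(node):
        if node.is_leaf():
            clusters.append(([node.id], 0.0))
            return
        child_top = max(node.left.dist, node.right.dist)
        gap = node.dist - child_top
        # clusters completing above max_cluster_height are never cohesive;
        # keep descending until the subtree drops below it
        if (
            node.dist > cut_height
            or node.dist > max_cluster_height
            or (node.dist > 0 and gap > gap_frac * node.dist)
        ):
            recurse(node.left)
            recurse(node.right)
        else:
            clusters.append((node.pre_order(lambda x: x.id), node.dist))

    recurse(root)

    modules = [
        sorted(members)
        for members, height in clusters
        if len(members) >= min_module_size and height <= max_cluster_height
    ]
    modules.sort(key=lambda m: (-len(m), m[0]))
    labels = pd.Series(GREY, index=gene_ids)
    for rank, members in enumerate(modules, start=1):
        labels.iloc[members] = f"M{rank}"
    return labels


def module_eigengene(profile: ExpressionProfile, module_labels: pd.Series) -> pd.DataFrame:
    """First principal component per module, over samples.

    Genes are standardized across samples before the SVD. Each eigengene has
    unit norm and its sign is chosen so that it correlates non-negatively with
    the module's average standardized expression.
    """
    eigengenes = {}
    for module_id in sorted(set(module_labels) - {GREY}):
        genes = module_labels.index[module_labels == module_id]
        if len(genes) < 2:
            raise ValueError(f"module {module_id} has fewer than 2 genes")
        x = profile.values.loc[genes].to_numpy(dtype=float)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        if np.all(sd == 0):
            raise ValueError(f"module {module_id} is degenerate (all genes constant)")
        xs = (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
        _, _, vt = np.linalg.svd(xs, full_matrices=False)
        eg = vt[0]
        if eg @ xs.mean(axis=0) < 0:
            eg = -eg
        eigengenes[module_id] = eg
    return pd.DataFrame(eigengenes, index=profile.sample_ids).T


def module_trait_stats(
    eigengenes: pd.DataFrame, group: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Pearson correlation of each eigengene with the 0/1 trait, plus p-value.

    The p-value comes from the exact t transform t = r sqrt((n-2)/(1-r^2))
    with n - 2 degrees of freedom, two-sided.
    """
    g = group.reindex(eigengenes.columns).to_numpy(dtype=float)
    if len(g) < 3:
        raise ValueError("module-trait statistics need >= 3 samples")
    r_out, p_out = {}, {}
    for module_id, eg in eigengenes.iterrows():
        e = eg.to_numpy(dtype=float)
        if np.std(e) == 0:
            raise ValueError(f"constant eigengene for module {module_id}")
        r, p = stats.pearsonr(e, g)
        r_out[module_id] = r
        p_out[module_id] = p
    return pd.Series(r_out), pd.Series(p_out)


def select_trait_module(result: CoexpressionResult) -> tuple[str, list[str]]:
    """The non-grey module with the largest |trait correlation|.

    Ties break toward the larger module, then the lexicographically smaller
    id. Returns the module id and its member genes.
    """
    candidates = [m for m in result.module_trait_r.index if m != GREY]
    if not candidates:
        raise ValueError("no non-grey modules to select from")
    sizes = result.module_labels.value_counts()

    def key(m):
        return (-abs(result.module_trait_r[m]), -sizes.get(m, 0), m)

    best = min(candidates, key=key)
    return best, result.module_members(best)


def run_coexpression(
    profile: ExpressionProfile,
    betas=tuple(range(1, 21)),
    r2_target: float = 0.85,
    min_module_size: int = 20,
    **cut_kwargs,
) -> tuple[CoexpressionResult, pd.DataFrame]:
    """Full co-expression stage: soft threshold, TOM, modules, eigengenes.

    Returns the CoexpressionResult and the soft-threshold scan table.
    """
    scan, beta = pick_soft_threshold(profile, betas=betas, r2_target=r2_target)
    adj = adjacency(profile, beta)
    tom = tom_similarity(adj)
    labels = detect_modules(tom, min_module_size=min_module_size, **cut_kwargs)
    if set(labels) == {GREY}:
        eigengenes = pd.DataFrame(columns=profile.sample_ids)
        r = pd.Series(dtype=float)
        p = pd.Series(dtype=float)
    else:
        eigengenes = module_eigengene(profile, labels)
        r, p = module_trait_stats(eigengenes, profile.group)
    return CoexpressionResult(labels, eigengenes, r, p, beta), scan
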