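"""Weighted co-expression network construction and module detection.

The network is unsigned: connection weights are a(i,j) = |corr(i,j)|^beta with
Pearson correlation of gene profiles.  Topological overlap combines direct
adjacency with shared-neighbor structure,

    W(i,j) = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_d a_id a_dj  (d != i, j),
    k_i    = sum_d a_id,

with W(i,i) = 1.  Genes are clustered on the distance D = 1 - W with
average-linkage hierarchical clustering, the dendrogram is cut with an
adaptive branch-decomposition rule, each module is summarized by its
eigengene (first principal component of the standardized member profiles),
and modules whose eigengenes correlate above the merge threshold are fused
iteratively with eigengene recomputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .iohub import ExpressionMatrix

logger = logging.getLogger(__name__)

GREY = "grey"  #: reserved label for genes assigned to no module


def _as_frame(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def log_expression(expr: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """The network-analysis transform: log2(x + 1)."""
    return np.log2(_as_frame(expr) + 1.0)


def gene_correlation(data: pd.DataFrame) -> np.ndarray:
    """Pearson correlation between gene rows; constant genes get 0 with a
    warning."""
    arr = data.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("%d constant gene(s): correlations set to 0", const.sum())
    safe = arr.copy()
    safe[const] = np.random.default_rng(0).normal(size=(const.sum(), arr.shape[1]))
    corr = np.corrcoef(safe)
    corr[const, :] = 0.0
    corr[:, const] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    return corr


def soft_adjacency(
    expr: ExpressionMatrix | pd.DataFrame,
    beta: float = 6.0,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a(i,j) = |corr(i,j)|^beta, zero
    diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    data = log_expression(expr) if log_transform else _as_frame(expr)
    if data.shape[1] < 3:
        raise ValueError("need at least three samples")
    corr = gene_correlation(data)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=data.index, columns=data.index)


def scale_free_fit_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of the binned connectivity distribution —
    the scale-free topology fit index."""
    k = connectivity[connectivity > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return 0.0
    counts, edges = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = counts > 0
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / counts.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def pick_beta(
    expr: ExpressionMatrix | pd.DataFrame,
    candidates: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.8,
    fallback: float = 6.0,
) -> float:
    """Smallest candidate beta reaching the scale-free fit target; fallback
    (with a warning) if none qualifies."""
    if not candidates:
        raise ValueError("no candidate beta values")
    data = log_expression(expr)
    corr = np.abs(gene_correlation(data))
    for beta in candidates:
        adj = corr**beta
        np.fill_diagonal(adj, 0.0)
        r2 = scale_free_fit_r2(adj.sum(axis=1))
        if r2 >= r2_target:
            logger.info("selected beta=%s (scale-free R^2=%.3f)", beta, r2)
            return float(beta)
    logger.warning(
        "no candidate beta reached scale-free R^2 >= %.2f; using fallback %s",
        r2_target, fallback,
    )
    return float(fallback)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a zero-diagonal adjacency in [0, 1].

    An isolated pair (k_i = k_j = 0, a_ij = 0) gets W = 0; the diagonal is 1.
    """
    a = adj.to_numpy(dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # a_ii = 0 removes d in {i, j} from the sum
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (l + a) / denom
    w[~np.isfinite(w)] = 0.0
    np.fill_diagonal(w, 1.0)
    np.clip(w, 0.0, 1.0, out=w)
    return pd.DataFrame(w, index=adj.index, columns=adj.columns)


def tom_distance(tom: pd.DataFrame) -> pd.DataFrame:
    """D = 1 - W with a zero diagonal."""
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, 1.0, out=d)
    return pd.DataFrame(d, index=tom.index, columns=tom.columns)


@dataclass
class Module:
    """A co-expressed gene module with its eigengene summary."""

    module_id: str
    genes: list[str]
    eigengene: pd.Series | None = None  # unit-norm, over samples
    var_explained: float = float("nan")
    stage: str | None = None
    stage_stats: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return len(self.genes)


def module_eigengene(
    expr: ExpressionMatrix | pd.DataFrame,
) -> tuple[pd.Series, float]:
    """First principal component of the standardized module expression.

    Returns the unit-norm eigengene over samples (sign aligned with the
    module's mean standardized profile) and the variance-explained fraction.
    """
    df = _as_frame(expr)
    if df.shape[0] == 0:
        raise ValueError("empty module")
    if df.shape[1] < 2:
        raise ValueError("need at least two samples")
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    if not ok.any():
        raise ValueError("all module genes are constant; eigengene undefined")
    z = (arr[ok] - arr[ok].mean(axis=1, keepdims=True)) / sd[ok]
    _u, s, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return pd.Series(v, index=df.columns, name="eigengene"), var_explained


def cluster_and_cut(
    distance: pd.DataFrame,
    min_module_size: int = 30,
    tight_frac: float = 0.9,
) -> tuple[list[Module], pd.Series]:
    """Average-linkage clustering of the TOM distance plus an adaptive branch
    cut.

    Branches are harvested top-down from the dendrogram: a subtree becomes a
    module when it is *tight* — every merge inside it, including its root,
    happens below ``tight_frac`` of the maximum merge height — and it has at
    least ``min_module_size`` genes.  Loose subtrees are split recursively;
    whatever never lands in a qualifying branch stays grey.  When all
    pairwise distances are equal there is no tight structure and every gene
    is grey.  Modules are labeled M1, M2, ... by decreasing size.

    Returns the module list and a gene -> label Series (grey = unassigned).
    """
    genes = list(distance.index)
    labels = pd.Series(GREY, index=pd.Index(genes, name="gene_id"))
    if len(genes) < min_module_size:
        logger.warning(
            "fewer genes (%d) than min_module_size (%d): all grey",
            len(genes), min_module_size,
        )
        return [], labels

    d = distance.to_numpy(dtype=float)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    linkage = hierarchy.linkage(squareform(d, checks=False), method="average")
    max_h = linkage[:, 2].max()
    if max_h <= 0:
        return [], labels
    cut_h = tight_frac * max_h

    # iterative top-down harvest of maximal tight branches
    root = hierarchy.to_tree(linkage)
    modules: list[Module] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.get_count() < min_module_size:
            continue
        if node.dist < cut_h:  # tight: all internal merges below the cut
            idx = node.pre_order(lambda leaf: leaf.id)
            modules.append(Module(module_id="", genes=[genes[i] for i in idx]))
        else:
            stack.extend((node.get_left(), node.get_right()))

    modules.sort(key=lambda m: (-m.size, m.genes[0]))
    for rank, mod in enumerate(modules):
        mod.module_id = f"M{rank + 1}"
        labels.loc[mod.genes] = mod.module_id
    return modules, labels


def attach_eigengenes(
    modules: list[Module], expr: ExpressionMatrix | pd.DataFrame,
    log_transform: bool = True,
) -> None:
    """Compute and store each module's eigengene from the analysis matrix."""
    data = log_expression(expr) if log_transform else _as_frame(expr)
    for mod in modules:
        eg, ve = module_eigengene(data.loc[mod.genes])
        mod.eigengene, mod.var_explained = eg, ve


def merge_modules(
    modules: list[Module],
    expr: ExpressionMatrix | pd.DataFrame,
    merge_threshold: float = 0.7,
    log_transform: bool = True,
) -> list[Module]:
    """Iteratively merge the module pair with the highest eigengene
    correlation strictly above the threshold, recomputing the merged
    eigengene, until no pair qualifies.  Labels are reassigned M1.. by size.
    """
    data = log_expression(expr) if log_transform else _as_frame(expr)
    work = [Module(m.module_id, list(m.genes)) for m in modules]
    for m in work:
        m.eigengene, m.var_explained = module_eigengene(data.loc[m.genes])

    while len(work) > 1:
        egs = np.vstack([m.eigengene.to_numpy() for m in work])
        corr = np.corrcoef(egs)
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= merge_threshold:
            break
        lo, hi = sorted((i, j))
        merged = Module(
            module_id=work[lo].module_id,
            genes=sorted(work[lo].genes + work[hi].genes),
        )
        merged.eigengene, merged.var_explained = module_eigengene(
            data.loc[merged.genes]
        )
        work = [m for k, m in enumerate(work) if k not in (lo, hi)] + [merged]

    work.sort(key=lambda m: (-m.size, m.genes[0]))
    for rank, mod in enumerate(work):
        mod.module_id = f"M{rank + 1}"
    return work


def prune_members(
    modules: list[Module],
    expr: ExpressionMatrix | pd.DataFrame,
    prune_kme: float = 0.3,
    log_transform: bool = True,
) -> list[Module]:
    """Drop members whose correlation with the module eigengene (kME) falls
    below ``prune_kme`` and recompute the eigengene.

    Dendrogram branches pick up stragglers whose profiles merely brush the
    branch; membership is re-certified against the eigengene, the module's
    own summary.  Modules shrinking below 3 genes are dropped.
    """
    data = log_expression(expr) if log_transform else _as_frame(expr)
    kept: list[Module] = []
    for mod in modules:
        eg, _ve = module_eigengene(data.loc[mod.genes])
        egz = (eg - eg.mean()) / eg.std()
        sub = data.loc[mod.genes].to_numpy(dtype=float)
        sd = sub.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
            kme = z @ egz.to_numpy() / len(egz)
        kme[sd == 0] = 0.0
        members = [g for g, k in zip(mod.genes, kme) if k >= prune_kme]
        if len(members) < 3:
            logger.warning("module %s dissolved by kME pruning", mod.module_id)
            continue
        pruned = Module(mod.module_id, members)
        pruned.eigengene, pruned.var_explained = module_eigengene(data.loc[members])
        kept.append(pruned)
    return kept


def detect_modules(
    expr: ExpressionMatrix | pd.DataFrame,
    beta: float | None = None,
    min_module_size: int = 30,
    merge_threshold: float = 0.7,
    prune_kme: float = 0.3,
) -> tuple[list[Module], pd.Series, pd.DataFrame]:
    """Full module-detection pipeline: adjacency -> TOM -> distance ->
    cluster/cut -> eigengenes -> merge -> kME pruning.

    Returns (modules, gene labels, TOM matrix).  ``beta=None`` triggers the
    scale-free criterion.
    """
    if beta is None:
        beta = pick_beta(expr)
    adj = soft_adjacency(expr, beta=beta)
    tom = topological_overlap(adj)
    dist = tom_distance(tom)
    modules, _labels = cluster_and_cut(dist, min_module_size=min_module_size)
    modules = merge_modules(modules, expr, merge_threshold=merge_threshold)
    modules = prune_members(modules, expr, prune_kme=prune_kme)
    modules.sort(key=lambda m: (-m.size, m.genes[0]))
    for rank, mod in enumerate(modules):
        mod.module_id = f"M{rank + 1}"
    labels = pd.Series(GREY, index=pd.Index(list(_as_frame(expr).index), name="gene_id"))
    for mod in modules:
        labels.loc[mod.genes] = mod.module_id
    return modules, labels, tom
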