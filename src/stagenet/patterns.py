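"""Sample-similarity QC and expression-pattern analysis.

Covers the Pearson sample-correlation matrix, PCA of samples, K-means
clustering of differentially expressed gene profiles with correlation-based
Bonferroni-corrected pattern assignment, and stage-enriched gene windows
(genes expressed only within a contiguous run of stages).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .iohub import ExpressionMatrix, StageDesign

logger = logging.getLogger(__name__)


def _log_transform(df: pd.DataFrame) -> pd.DataFrame:
    return np.log2(df + 1.0)


def sample_correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between sample columns on log2(x+1) values."""
    if expr.n_samples < 2:
        raise ValueError("need at least two samples")
    log = _log_transform(expr.values)
    sds = log.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = sds.index[sds == 0][0]
        raise ValueError(f"sample {bad!r} is constant; correlation undefined")
    corr = np.corrcoef(log.to_numpy().T)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=log.columns, columns=log.columns)


def pca_embedding(
    expr: ExpressionMatrix, n_components: int = 3
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the top principal components of the centered
    log2(x+1) data.

    Returns (coordinates: samples x components, variance_explained fractions).
    The sign of each component is fixed so its largest-magnitude sample score
    is positive.
    """
    if n_components > expr.n_samples:
        raise ValueError("n_components exceeds the number of samples")
    log = _log_transform(expr.values).to_numpy().T  # samples x genes
    centered = log - log.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    var = s**2
    var_explained = (var / var.sum())[:n_components] if var.sum() > 0 else var[:n_components]
    frame = pd.DataFrame(
        coords,
        index=expr.sample_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, var_explained


@dataclass
class PatternClustering:
    """K-means pattern clusters with per-gene correlation-based assignment.

    ``centroids``: clusters x samples, standardized (zero mean, unit variance
    across samples).  ``assignments``: per gene the assigned cluster (or
    <NA>), its correlation to that centroid and the Bonferroni-adjusted p.
    """

    k: int
    centroids: pd.DataFrame
    assignments: pd.DataFrame  # columns: cluster, r, p_adj


def _standardize_rows(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(arr)
    z[ok] = (arr[ok] - mean[ok]) / sd[ok]
    return z, ok


def correlation_test_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson correlation via the t statistic, df = n - 2."""
    df = n - 2
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def kmeans_patterns(
    expr: ExpressionMatrix | pd.DataFrame,
    k: int = 30,
    seed: int = 0,
    n_init: int = 25,
    alpha: float = 0.05,
    bonferroni_family: int | None = None,
) -> PatternClustering:
    """Cluster standardized gene profiles with K-means, then assign each gene
    to its best-correlated centroid iff the Bonferroni-adjusted correlation
    p-value is below alpha.

    The Bonferroni multiplier defaults to genes x k (every correlation
    tested).  Cluster labels are canonicalized by descending cluster size,
    ties broken by the lexicographically smallest member gene.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if df.shape[0] < k:
        raise ValueError(f"need at least k={k} genes, got {df.shape[0]}")
    arr = df.to_numpy(dtype=float)
    z, ok = _standardize_rows(arr)
    if (~ok).any():
        logger.warning("%d constant gene profiles left unassigned", (~ok).sum())

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(z[ok])
    cents, cent_ok = _standardize_rows(km.cluster_centers_)
    if (~cent_ok).any():
        logger.warning("%d degenerate (constant) centroids", (~cent_ok).sum())

    n = df.shape[1]
    m = bonferroni_family if bonferroni_family is not None else df.shape[0] * k
    # correlation of standardized rows with standardized centroids
    rmat = z @ cents.T / n
    rmat[:, ~cent_ok] = 0.0
    best = np.argmax(rmat, axis=1)
    best_r = rmat[np.arange(len(best)), best]
    p_raw = correlation_test_p(best_r, n)
    p_adj = np.minimum(1.0, p_raw * m)
    assigned = ok & (p_adj < alpha)

    # canonical relabeling: descending size, tie-break smallest member gene
    sizes = np.bincount(best[assigned], minlength=k)
    first_member = []
    genes = np.asarray(df.index)
    for c in range(k):
        members = genes[assigned & (best == c)]
        first_member.append(min(members) if len(members) else "￿")
    order = sorted(range(k), key=lambda c: (-sizes[c], first_member[c]))
    relabel = {old: f"C{rank + 1}" for rank, old in enumerate(order)}

    cluster_col = pd.array(
        [relabel[b] if a else pd.NA for a, b in zip(assigned, best)],
        dtype="string",
    )
    assignments = pd.DataFrame(
        {"cluster": cluster_col, "r": best_r, "p_adj": p_adj}, index=df.index
    )
    assignments.loc[~ok, ["r", "p_adj"]] = np.nan
    centroids = pd.DataFrame(
        cents[order], index=[f"C{i + 1}" for i in range(k)], columns=df.columns
    )
    return PatternClustering(k=k, centroids=centroids, assignments=assignments)


@dataclass
class StageEnrichedSet:
    """Genes expressed only within one contiguous window of stages."""

    window: tuple[str, ...]
    genes: set[str]


def stage_enriched_genes(
    fpkm: ExpressionMatrix,
    design: StageDesign,
    window: tuple[str, ...] | list[str],
    on_threshold: float = 0.1,
    fold: float = 5.0,
) -> StageEnrichedSet:
    """Genes detected in every stage of the window, silent outside it.

    A gene qualifies if its mean FPKM exceeds ``on_threshold`` at every window
    stage, the mean-inside / mean-outside ratio is at least ``fold``, and the
    mean outside the window does not exceed ``on_threshold``.
    """
    window = tuple(window)
    if not window:
        raise ValueError("empty stage window")
    idx = [design.stages.index(s) for s in window]  # raises on unknown stage
    if idx != list(range(min(idx), min(idx) + len(idx))):
        raise ValueError("window must be a contiguous run of the stage order")
    stage_means = pd.DataFrame(
        {s: fpkm.values[design.samples_for(s)].mean(axis=1) for s in design.stages}
    )
    inside = stage_means[list(window)]
    outside_stages = [s for s in design.stages if s not in window]
    on_everywhere_in = (inside > on_threshold).all(axis=1)
    mean_in = inside.mean(axis=1)
    if outside_stages:
        mean_out = stage_means[outside_stages].mean(axis=1)
        with np.errstate(divide="ignore"):
            ratio_ok = mean_in >= fold * mean_out
        quiet_out = mean_out <= on_threshold
    else:
        ratio_ok = pd.Series(True, index=stage_means.index)
        quiet_out = ratio_ok
    keep = on_everywhere_in & ratio_ok & quiet_out
    return StageEnrichedSet(window=window, genes=set(stage_means.index[keep]))


def default_windows(design: StageDesign) -> list[tuple[str, ...]]:
    """The canonical windows examined in early-embryo series: first stage
    only, first-to-mid run, mid-to-last run, last stage only."""
    s = design.stages
    return [
        (s[0],),
        tuple(s[0:3]),
        tuple(s[3:]),
        (s[-1],),
    ]
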