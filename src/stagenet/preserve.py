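"""Permutation-based module-preservation Z statistics between a reference and
a test expression dataset.

For each module, four observed statistics are computed on the ortholog-mapped
common gene background:

* meanCor — mean off-diagonal intramodular correlation magnitude (test data);
* meanAdj — mean off-diagonal soft-threshold adjacency (test data);
* cor_kIM — correlation of intramodular connectivity, reference vs test;
* cor_cor — correlation of the vectorized upper-triangle correlation
  matrices, reference vs test.

Each is standardized against a permutation null of random same-size gene sets
drawn (without replacement, excluding the module's own genes) from the common
background: Z = (obs - perm_mean) / perm_sd.  Then

    Zdensity      = median(Z_meanCor, Z_meanAdj)
    Zconnectivity = median(Z_cor_kIM, Z_cor_cor)
    Zsummary      = (Zdensity + Zconnectivity) / 2

with the categorical calls: strong if Zsummary >= 10, weak-to-moderate if
2 <= Zsummary < 10, none if Zsummary < 2.

This is a four-statistic variant of the published permutation Z-statistic
battery; numerical equivalence with the WGCNA reference implementation is not
claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iohub import ExpressionMatrix, OrthologMap
from .netcore import Module, log_expression

logger = logging.getLogger(__name__)

CATEGORY_STRONG = "strong"
CATEGORY_WEAK = "weak-moderate"
CATEGORY_NONE = "none"
CATEGORY_UNTESTABLE = "untestable"


def categorize(zsummary: float) -> str:
    if zsummary >= 10:
        return CATEGORY_STRONG
    if zsummary >= 2:
        return CATEGORY_WEAK
    return CATEGORY_NONE


@dataclass
class PreservationReport:
    module_id: str
    size: int
    z_density: float
    z_connectivity: float
    z_summary: float
    category: str
    n_perm: int
    seed: int
    observed: dict[str, float] | None = None


def _module_stats(
    ref: np.ndarray, test: np.ndarray, beta: float
) -> tuple[float, float, float, float]:
    """(meanCor, meanAdj, cor_kIM, cor_cor) for one gene set (rows = genes)."""
    m = ref.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        cor_ref = np.corrcoef(ref)
        cor_test = np.corrcoef(test)
    cor_ref = np.nan_to_num(cor_ref)
    cor_test = np.nan_to_num(cor_test)
    iu = np.triu_indices(m, k=1)
    mean_cor = float(np.abs(cor_test[iu]).mean())
    adj_test = np.abs(cor_test) ** beta
    np.fill_diagonal(adj_test, 0.0)
    mean_adj = float(adj_test[iu].mean())
    adj_ref = np.abs(cor_ref) ** beta
    np.fill_diagonal(adj_ref, 0.0)
    k_ref = adj_ref.sum(axis=1)
    k_test = adj_test.sum(axis=1)
    cor_kim = _safe_corr(k_ref, k_test)
    cor_cor = _safe_corr(cor_ref[iu], cor_test[iu])
    return mean_cor, mean_adj, cor_kim, cor_cor


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def preservation_z(
    ref_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    modules: list[Module],
    ortholog_map: OrthologMap | None = None,
    ref_species: str = "speciesA",
    test_species: str = "speciesB",
    beta: float = 6.0,
    n_perm: int = 200,
    seed: int = 0,
) -> list[PreservationReport]:
    """Preservation Z statistics of reference modules in a test dataset.

    With an ortholog map, reference genes are translated to test genes through
    their ortholog groups; without one, shared gene IDs are used.  Modules
    reduced below 3 common genes are reported as untestable.
    """
    ref_log = log_expression(ref_expr)
    test_log = log_expression(test_expr)

    if ortholog_map is not None:
        ref_to_group = ortholog_map.gene_to_group(ref_species)
        group_to_test = ortholog_map.group_to_genes(test_species)
        translate: dict[str, str] = {}
        test_genes = set(test_log.index)
        for gene in ref_log.index:
            grp = ref_to_group.get(gene)
            if grp is None:
                continue
            for cand in group_to_genes_sorted(group_to_test, grp):
                if cand in test_genes:
                    translate[gene] = cand
                    break
    else:
        translate = {g: g for g in ref_log.index if g in set(test_log.index)}

    # commonly *expressed* orthologs: silent (zero-variance) genes carry no
    # correlation structure and would deflate the permutation null
    ref_var = ref_log.var(axis=1)
    test_var = test_log.var(axis=1)
    background = [
        g
        for g in ref_log.index
        if g in translate and ref_var[g] > 0 and test_var[translate[g]] > 0
    ]
    if len(background) < 30:
        raise ValueError(
            f"only {len(background)} common ortholog-mapped genes (need >= 30)"
        )
    bg_index = {g: i for i, g in enumerate(background)}
    ref_arr = ref_log.loc[background].to_numpy(dtype=float)
    test_arr = test_log.loc[[translate[g] for g in background]].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    reports = []
    for mod in modules:
        members = [g for g in mod.genes if g in bg_index]
        if len(members) < 3:
            logger.warning("module %s untestable (%d common genes)",
                           mod.module_id, len(members))
            reports.append(
                PreservationReport(
                    mod.module_id, len(members), np.nan, np.nan, np.nan,
                    CATEGORY_UNTESTABLE, n_perm, seed,
                )
            )
            continue
        midx = np.array([bg_index[g] for g in members])
        obs = np.array(_module_stats(ref_arr[midx], test_arr[midx], beta))

        pool = np.array([i for g, i in bg_index.items() if g not in set(members)])
        if len(pool) < len(midx):
            pool = np.arange(len(background))  # tiny background: allow overlap
        perm = np.empty((n_perm, 4))
        for p in range(n_perm):
            pick = rng.choice(pool, size=len(midx), replace=False)
            perm[p] = _module_stats(ref_arr[pick], test_arr[pick], beta)
        mu = perm.mean(axis=0)
        sd = perm.std(axis=0, ddof=1)
        sd = np.maximum(sd, 1e-12)
        z = (obs - mu) / sd
        z_density = float(np.median(z[:2]))
        z_connectivity = float(np.median(z[2:]))
        z_summary = 0.5 * (z_density + z_connectivity)
        reports.append(
            PreservationReport(
                mod.module_id,
                len(members),
                z_density,
                z_connectivity,
                z_summary,
                categorize(z_summary),
                n_perm,
                seed,
                observed=dict(
                    zip(("meanCor", "meanAdj", "cor_kIM", "cor_cor"), obs)
                ),
            )
        )
    return reports


def group_to_genes_sorted(group_to_test: dict[str, list[str]], grp: str) -> list[str]:
    """Deterministic candidate order for many-to-many ortholog groups."""
    return sorted(group_to_test.get(grp, []))


def preservation_heatmap_table(
    reports_by_dataset: dict[str, list[PreservationReport]],
) -> pd.DataFrame:
    """Modules x datasets table of Zsummary values; untestable cells are NA."""
    modules: list[str] = []
    for reps in reports_by_dataset.values():
        for r in reps:
            if r.module_id not in modules:
                modules.append(r.module_id)
    table = pd.DataFrame(index=modules, columns=list(reports_by_dataset), dtype=float)
    for ds, reps in reports_by_dataset.items():
        for r in reps:
            if r.category != CATEGORY_UNTESTABLE:
                table.loc[r.module_id, ds] = r.z_summary
    return table
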