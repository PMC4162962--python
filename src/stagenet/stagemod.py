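"""Stage-specific module calling, hub-gene identification and hub-network
export.

A module is specific to a developmental stage when its eigengene correlates
positively (P < 0.05, t test with df = n_samples - 2) with the stage's unit
indicator vector; among qualifying stages the single best positive
correlation wins.  Hub genes are module members whose kME — correlation of
the gene's profile with the module eigengene — is strictly greater than 0.9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iohub import ExpressionMatrix, OrthologMap, StageDesign, write_edge_list
from .netcore import Module, log_expression
from .patterns import correlation_test_p

logger = logging.getLogger(__name__)


@dataclass
class StageSpecificCall:
    """Per-stage eigengene/indicator correlations and the assigned stage."""

    module_id: str
    stats: pd.DataFrame  # index: stage; columns: r, pvalue
    stage: str | None


def stage_specific_modules(
    modules: list[Module],
    design: StageDesign,
    alpha: float = 0.05,
) -> list[StageSpecificCall]:
    """Label each module with the stage its eigengene indicates, if any."""
    if len(design.stages) < 2:
        raise ValueError("need at least two stages")
    calls = []
    for mod in modules:
        if mod.eigengene is None:
            raise ValueError(f"module {mod.module_id} has no eigengene")
        samples = list(mod.eigengene.index)
        eg = mod.eigengene.to_numpy()
        n = len(samples)
        rows = {}
        if np.std(eg) == 0:
            logger.warning("module %s has a constant eigengene", mod.module_id)
            stats_df = pd.DataFrame(
                {"r": np.nan, "pvalue": np.nan}, index=list(design.stages)
            )
            calls.append(StageSpecificCall(mod.module_id, stats_df, None))
            continue
        for stage in design.stages:
            ind = design.indicator(stage, samples)
            if ind.std() == 0:
                rows[stage] = (np.nan, np.nan)
                continue
            r = float(np.corrcoef(eg, ind)[0, 1])
            p = float(correlation_test_p(np.array([r]), n)[0])
            rows[stage] = (r, p)
        stats_df = pd.DataFrame(rows, index=["r", "pvalue"]).T
        qualifying = stats_df[(stats_df["pvalue"] < alpha) & (stats_df["r"] > 0)]
        stage = qualifying["r"].idxmax() if not qualifying.empty else None
        mod.stage, mod.stage_stats = stage, stats_df
        calls.append(StageSpecificCall(mod.module_id, stats_df, stage))
    return calls


@dataclass
class HubGene:
    gene_id: str
    module_id: str
    kme: float


def gene_kme(
    module: Module, expr: ExpressionMatrix | pd.DataFrame, log_transform: bool = True
) -> pd.Series:
    """kME of every member gene: Pearson correlation with the eigengene."""
    if module.eigengene is None:
        raise ValueError("module eigengene not computed")
    data = log_expression(expr) if log_transform else (
        expr.values if isinstance(expr, ExpressionMatrix) else expr
    )
    sub = data.loc[module.genes].to_numpy(dtype=float)
    eg = module.eigengene.to_numpy()
    egz = (eg - eg.mean()) / eg.std()
    sd = sub.std(axis=1)
    mean = sub.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (sub - mean[:, None]) / sd[:, None]
        kme = z @ egz / len(eg)
    kme[sd == 0] = 0.0
    return pd.Series(np.clip(kme, -1, 1), index=module.genes, name="kME")


def hub_genes(
    module: Module,
    expr: ExpressionMatrix | pd.DataFrame,
    kme_threshold: float = 0.9,
    log_transform: bool = True,
) -> list[HubGene]:
    """Members with kME strictly greater than the threshold, sorted by kME
    descending (ties broken lexicographically by gene ID)."""
    kme = gene_kme(module, expr, log_transform=log_transform)
    hubs = kme[kme > kme_threshold]
    ordered = sorted(hubs.items(), key=lambda kv: (-kv[1], kv[0]))
    return [HubGene(g, module.module_id, float(v)) for g, v in ordered]


def hub_network_export(
    module: Module,
    weights: pd.DataFrame,
    expr: ExpressionMatrix | pd.DataFrame,
    n_hubs: int = 150,
    n_edges: int = 200,
    kme_threshold: float = 0.9,
    log_transform: bool = True,
    path=None,
) -> list[tuple[str, str, float]]:
    """Top-``n_edges`` strongest pairwise connections among the top-``n_hubs``
    hub genes of a module, from a gene x gene weight matrix (TOM by default
    upstream).  Deterministic: ties broken by lexicographic node pair.
    Optionally written as a VisANT-compatible edge list.
    """
    hubs = hub_genes(module, expr, kme_threshold=kme_threshold,
                     log_transform=log_transform)
    top = [h.gene_id for h in hubs[:n_hubs]]
    if len(top) < 2:
        logger.warning(
            "module %s has %d hub gene(s); empty edge list", module.module_id, len(top)
        )
        edges: list[tuple[str, str, float]] = []
    else:
        cand = []
        for i, a in enumerate(top):
            for b in top[i + 1:]:
                lo, hi = sorted((a, b))
                cand.append((-float(weights.loc[a, b]), lo, hi))
        cand.sort()
        edges = [(lo, hi, -negw) for negw, lo, hi in cand[:n_edges]]
    if path is not None:
        write_edge_list(edges, path)
    return edges


def validate_hubs_across_datasets(
    hub_tables: dict[str, pd.DataFrame],
    ortholog_map: OrthologMap,
    species_of: dict[str, str],
) -> pd.DataFrame:
    """Cross-dataset hub validation.

    ``hub_tables`` maps dataset name -> DataFrame with columns ``gene_id``,
    ``module_id``, ``stage``.  A hub is validated when its ortholog group
    appears among the hubs of a same-stage module in at least one other
    dataset.  Unmapped genes are skipped and counted.

    Returns one row per (dataset, module): n_hubs, n_validated, pct_validated,
    n_unmapped.
    """
    # (dataset, stage) -> set of ortholog groups with a hub there
    groups_by_ds_stage: dict[tuple[str, str], set[str]] = {}
    mapped: dict[str, pd.DataFrame] = {}
    for ds, table in hub_tables.items():
        g2g = ortholog_map.gene_to_group(species_of[ds])
        t = table.copy()
        t["group"] = t["gene_id"].map(g2g)
        mapped[ds] = t
        for stage, sub in t.dropna(subset=["group"]).groupby("stage"):
            groups_by_ds_stage.setdefault((ds, stage), set()).update(sub["group"])

    rows = []
    for ds, t in mapped.items():
        for (module_id, stage), sub in t.groupby(["module_id", "stage"]):
            unmapped = sub["group"].isna()
            others: set[str] = set()
            for other_ds in hub_tables:
                if other_ds != ds:
                    others |= groups_by_ds_stage.get((other_ds, stage), set())
            validated = sub.loc[~unmapped, "group"].isin(others)
            n_hubs = len(sub)
            n_val = int(validated.sum())
            rows.append(
                {
                    "dataset": ds,
                    "module_id": module_id,
                    "stage": stage,
                    "n_hubs": n_hubs,
                    "n_validated": n_val,
                    "pct_validated": 100.0 * n_val / n_hubs if n_hubs else np.nan,
                    "n_unmapped": int(unmapped.sum()),
                }
            )
    return pd.DataFrame(rows)
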