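"""Cross-species module comparison on a shared ortholog background.

Modules from two species are intersected at the ortholog-group level and each
pair is tested for overlap enrichment with a one-sided Fisher exact
(hypergeometric upper-tail) test; the -log10 P table mirrors the classic
module-overlap heatmap, one cell per (module A, module B) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iohub import OrthologMap

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class OrthologBackground:
    """Ortholog groups expressed in both species of a pair, with each
    species' gene -> group map restricted to the background."""

    species_a: str
    species_b: str
    groups: set[str]
    gene_to_group_a: dict[str, str]
    gene_to_group_b: dict[str, str]

    def map_module(self, genes: Iterable[str], species: str) -> set[str]:
        g2g = (
            self.gene_to_group_a if species == self.species_a else self.gene_to_group_b
        )
        return {g2g[g] for g in genes if g in g2g}


def common_ortholog_background(
    expressed: Mapping[str, Iterable[str]],
    ortholog_map: OrthologMap,
    species_a: str,
    species_b: str,
) -> OrthologBackground:
    """Ortholog groups with an expressed member in both species."""
    maps = {}
    groups_expressed = {}
    for sp in (species_a, species_b):
        g2g = ortholog_map.gene_to_group(sp)
        exp = set(expressed[sp])
        maps[sp] = {g: grp for g, grp in g2g.items() if g in exp}
        groups_expressed[sp] = set(maps[sp].values())
    common = groups_expressed[species_a] & groups_expressed[species_b]
    if not common:
        raise ValueError(
            f"no commonly expressed ortholog groups between {species_a} and {species_b}"
        )
    return OrthologBackground(
        species_a=species_a,
        species_b=species_b,
        groups=common,
        gene_to_group_a={g: grp for g, grp in maps[species_a].items() if grp in common},
        gene_to_group_b={g: grp for g, grp in maps[species_b].items() if grp in common},
    )


@dataclass
class OverlapCell:
    module_a: str
    module_b: str
    n_a: int
    n_b: int
    intersection: int
    p_value: float
    neg_log10_p: float
    untestable: bool = False


def module_overlap_test(
    module_a_groups: set[str],
    module_b_groups: set[str],
    background: set[str],
    label_a: str = "A",
    label_b: str = "B",
) -> OverlapCell:
    """One-sided overlap-enrichment test of two group sets over a background.

    P = P(X >= observed) for X hypergeometric(N=|background|, K=|A|, n=|B|).
    """
    a = module_a_groups & background
    b = module_b_groups & background
    n_bg = len(background)
    if not a or not b:
        return OverlapCell(label_a, label_b, len(a), len(b), 0, 1.0, 0.0,
                           untestable=True)
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, n_bg, len(a), len(b)))
    p = min(max(p, P_FLOOR), 1.0)
    return OverlapCell(label_a, label_b, len(a), len(b), k, p, -np.log10(p))


def overlap_matrix(
    modules_a: Mapping[str, Iterable[str]],
    modules_b: Mapping[str, Iterable[str]],
    background: OrthologBackground,
) -> tuple[pd.DataFrame, pd.DataFrame, list[OverlapCell]]:
    """Test all (module A, module B) pairs.

    Module dicts map label -> member genes (in their own species' gene IDs);
    label order is preserved in the output (callers pass stage order).
    Returns (count table, -log10 P table, flat list of cells).
    """
    groups_a = {
        lab: background.map_module(genes, background.species_a)
        for lab, genes in modules_a.items()
    }
    groups_b = {
        lab: background.map_module(genes, background.species_b)
        for lab, genes in modules_b.items()
    }
    counts = pd.DataFrame(index=list(modules_a), columns=list(modules_b), dtype=float)
    neglog = counts.copy()
    cells = []
    for la, ga in groups_a.items():
        for lb, gb in groups_b.items():
            cell = module_overlap_test(ga, gb, background.groups, la, lb)
            cells.append(cell)
            counts.loc[la, lb] = cell.intersection
            neglog.loc[la, lb] = np.nan if cell.untestable else cell.neg_log10_p
    return counts, neglog, cells
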