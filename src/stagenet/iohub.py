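"""Readers/writers and core containers for every table the pipeline touches.

Dialect: UTF-8, tab-delimited, ``#`` comment lines, ``.`` decimal separator —
the conventions of GEO supplementary tables.  Gene and sample identifiers are
opaque strings (LOC-style IDs such as ``LOC100137763`` pass through verbatim).
Parsers fail fast on malformed data instead of coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default stage order of the bovine pre-implantation series: matured oocyte
#: through blastocyst, 8 stages.
DEFAULT_STAGES: tuple[str, ...] = (
    "oocyte",
    "2-cell",
    "4-cell",
    "8-cell",
    "16-cell",
    "early_morula",
    "compact_morula",
    "blastocyst",
)


class ParseError(ValueError):
    """Raised when an input table violates its documented dialect."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table, either raw counts or FPKM.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.  Counts must
        be non-negative integers; FPKM non-negative reals.
    kind
        ``"counts"`` or ``"fpkm"``.
    """

    values: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "fpkm"):
            raise ValueError(f"kind must be 'counts' or 'fpkm', got {self.kind!r}")
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        validate_expression_frame(self.values, self.kind)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), kind=self.kind)


def validate_expression_frame(df: pd.DataFrame, kind: str) -> None:
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate gene ID: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ParseError(f"duplicate sample ID: {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ParseError("non-numeric cell in expression table")
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ParseError(
            f"non-numeric cell at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ParseError(
            f"negative value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if kind == "counts" and not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ParseError(
            f"non-integral count at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )


@dataclass
class StageDesign:
    """Ordered developmental stages and the sample -> (stage, replicate) map."""

    stages: tuple[str, ...] = DEFAULT_STAGES
    assignments: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        seen = set()
        for sample, (stage, _rep) in self.assignments.items():
            if stage not in self.stages:
                raise ValueError(f"sample {sample!r} maps to unknown stage {stage!r}")
            seen.add(stage)
        for stage in self.stages:
            if self.assignments and stage not in seen:
                raise ValueError(f"stage {stage!r} has no samples")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage labels")

    @classmethod
    def balanced(
        cls,
        stages: Sequence[str] = DEFAULT_STAGES,
        n_replicates: int = 2,
    ) -> "StageDesign":
        """Design with ``n_replicates`` samples per stage, named ``stage_r<i>``."""
        assignments = {
            f"{stage}_r{rep}": (stage, rep)
            for stage in stages
            for rep in range(1, n_replicates + 1)
        }
        return cls(stages=tuple(stages), assignments=assignments)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    def samples_for(self, stage: str) -> list[str]:
        if stage not in self.stages:
            raise ValueError(f"unknown stage {stage!r}")
        return [s for s, (st, _r) in self.assignments.items() if st == stage]

    def stage_of(self, sample: str) -> str:
        return self.assignments[sample][0]

    def consecutive_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.stages[:-1], self.stages[1:]))

    def indicator(self, stage: str, samples: Sequence[str] | None = None) -> np.ndarray:
        """Unit indicator vector over samples: 1 at the given stage, 0 elsewhere."""
        samples = list(samples) if samples is not None else self.sample_ids
        members = set(self.samples_for(stage))
        return np.array([1.0 if s in members else 0.0 for s in samples])


@dataclass
class OrthologMap:
    """HomoloGene-style map: records of (group_id, species, gene_id).

    A (species, gene) pair belongs to at most one ortholog group.
    """

    records: pd.DataFrame  # columns: group_id, species, gene_id

    def __post_init__(self) -> None:
        req = ["group_id", "species", "gene_id"]
        if list(self.records.columns) != req:
            self.records = self.records[req]
        self.records = self.records.astype(str)
        dup = self.records.duplicated(subset=["species", "gene_id"], keep=False)
        if dup.any():
            conflicting = self.records[dup]
            key = tuple(conflicting.iloc[0][["species", "gene_id"]])
            if conflicting.groupby(["species", "gene_id"])["group_id"].nunique().max() > 1:
                raise ParseError(f"gene mapped to two ortholog groups: {key}")
            self.records = self.records.drop_duplicates()

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_groups(self) -> int:
        return self.records["group_id"].nunique()

    def gene_to_group(self, species: str) -> dict[str, str]:
        sub = self.records[self.records["species"] == species]
        return dict(zip(sub["gene_id"], sub["group_id"]))

    def group_to_genes(self, species: str) -> dict[str, list[str]]:
        sub = self.records[self.records["species"] == species]
        out: dict[str, list[str]] = {}
        for grp, gene in zip(sub["group_id"], sub["gene_id"]):
            out.setdefault(grp, []).append(gene)
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression(path, kind: str = "counts") -> ExpressionMatrix:
    """Read a tab-delimited expression table (header = sample IDs, first
    column = gene IDs)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric cell in {path}: {exc}") from exc
    return ExpressionMatrix(values, kind=kind)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values
    if matrix.kind == "counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> StageDesign:
    """Read a design table with columns sample_id, stage, replicate.

    Stage order is the order of first appearance.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    req = {"sample_id", "stage", "replicate"}
    if not req.issubset(df.columns):
        raise ParseError(f"design table must have columns {sorted(req)}")
    stages = tuple(dict.fromkeys(df["stage"]))
    assignments = {
        row.sample_id: (row.stage, int(row.replicate)) for row in df.itertuples()
    }
    if len(assignments) != len(df):
        raise ParseError("duplicate sample_id in design table")
    return StageDesign(stages=stages, assignments=assignments)


def write_design(design: StageDesign, path) -> None:
    rows = [
        {"sample_id": s, "stage": st, "replicate": r}
        for s, (st, r) in design.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> OrthologMap:
    """Read a 3-column tab-delimited ortholog map (group_id, species, gene_id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["group_id", "species", "gene_id"],
        dtype=str,
        skip_blank_lines=True,
    )
    df = df.dropna(how="all")
    if df.empty:
        logger.warning("ortholog map %s is empty", path)
        df = pd.DataFrame(columns=["group_id", "species", "gene_id"], dtype=str)
    return OrthologMap(df)


def write_ortholog_map(omap: OrthologMap, path) -> None:
    omap.records.to_csv(path, sep="\t", index=False, header=False)


def write_edge_list(edges: Iterable[tuple[str, str, float]], path) -> None:
    """Write a VisANT-loadable weighted edge list (node1, node2, weight).

    Rows are lexicographically sorted for byte-reproducibility; node pairs are
    canonicalized (smaller node first).  Self-edges and weights outside [0, 1]
    are rejected.
    """
    rows = []
    for a, b, w in edges:
        if a == b:
            raise ValueError(f"self-edge rejected: {a!r}")
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"edge weight {w} outside [0, 1] for ({a!r}, {b!r})")
        lo, hi = sorted((str(a), str(b)))
        rows.append((lo, hi, w))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#node1\tnode2\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def write_module_table(table: pd.DataFrame, path) -> None:
    """Write a per-gene module table (columns: module_id, kME, is_hub)."""
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_module_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes: Sequence[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")
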