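"""Core data containers shared by every pipeline stage.

All containers validate their invariants at construction time and raise
:class:`ValidationError` with a message naming the offending entry, so that
downstream code can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

CONDITIONS = ("HC", "ACD", "TCD")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, genes x units.

    ``unit_ids`` are cell barcodes or spot ids. Zero entries are never
    materialized; ``values`` is stored CSR.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    unit_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.unit_ids = [str(u) for u in self.unit_ids]
        if self.values.shape != (len(self.gene_ids), len(self.unit_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.unit_ids)} units"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.unit_ids, "unit id")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative count entries present")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer count entries present")
        self.values.eliminate_zeros()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def total(self) -> int:
        return int(self.values.sum())

    def unit_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return CountMatrix(self.values[rows, :], list(genes), list(self.unit_ids))

    def subset_units(self, units: Sequence[str]) -> "CountMatrix":
        idx = {u: i for i, u in enumerate(self.unit_ids)}
        cols = [idx[u] for u in units]
        return CountMatrix(self.values[:, cols], list(self.gene_ids), list(units))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.unit_ids == other.unit_ids
            and (self.values != other.values).nnz == 0
        )


ANNOTATION_COLUMNS = ["unit_id", "sample_id", "condition", "cluster"]


def validate_annotation(ann: pd.DataFrame, counts: Optional[CountMatrix] = None) -> pd.DataFrame:
    """Validate a unit annotation table (unit_id, sample_id, condition, cluster).

    ``cluster`` may be absent before clustering; it is added as NA if missing.
    """
    for col in ("unit_id", "sample_id", "condition"):
        if col not in ann.columns:
            raise FormatError(f"annotation missing mandatory column {col!r}")
    ann = ann.copy()
    if "cluster" not in ann.columns:
        ann["cluster"] = pd.NA
    if ann["unit_id"].duplicated().any():
        dup = ann.loc[ann["unit_id"].duplicated(), "unit_id"].iloc[0]
        raise ValidationError(f"duplicate unit_id in annotation: {dup!r}")
    bad = set(ann["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition labels: {sorted(bad)}")
    if counts is not None:
        missing = set(ann["unit_id"]) - set(counts.unit_ids)
        if missing:
            raise ValidationError(
                f"annotation unit ids absent from count matrix: {sorted(missing)[:5]}"
            )
    return ann


CLONOTYPE_COLUMNS = [
    "sample_id", "condition", "cluster", "v_call", "j_call",
    "cdr3_nt", "cdr3_aa", "count",
]


def validate_clonotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a clonotype table; returns a normalized copy."""
    for col in ("sample_id", "v_call", "j_call", "cdr3_aa", "count"):
        if col not in table.columns:
            raise FormatError(f"clonotype table missing mandatory column {col!r}")
    table = table.copy()
    if "cluster" not in table.columns:
        table["cluster"] = pd.NA
    if "cdr3_nt" not in table.columns:
        table["cdr3_nt"] = pd.NA
    if "condition" not in table.columns:
        table["condition"] = pd.NA
    if (table["count"] < 1).any():
        raise ValidationError("clonotype counts must be >= 1")
    return table


@dataclass
class SpatialDataset:
    """Spot lattice with counts and optional per-spot region labels."""

    spots: list[str]
    lattice: str  # "hex" (odd-row-shifted) or "square"
    array_row: np.ndarray
    array_col: np.ndarray
    counts: CountMatrix
    region: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.lattice not in ("hex", "square"):
            raise ValidationError(f"unknown lattice type {self.lattice!r}")
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        n = len(self.spots)
        if not (len(self.array_row) == len(self.array_col) == n):
            raise ValidationError("coordinate arrays do not match number of spots")
        coords = set(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(coords) != n:
            raise ValidationError("duplicate lattice coordinates")
        if self.counts.unit_ids != list(self.spots):
            raise ValidationError("counts unit_ids must equal spot ids in order")
        if self.region is not None and len(self.region) != n:
            raise ValidationError("region labels do not match number of spots")

    @property
    def n_spots(self) -> int:
        return len(self.spots)


@dataclass
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")


def validate_rl_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Validate a receptor-ligand pair list (ligand, receptor, pair_name)."""
    for col in ("ligand", "receptor", "pair_name"):
        if col not in pairs.columns:
            raise FormatError(f"pair list missing mandatory column {col!r}")
    if pairs["pair_name"].duplicated().any():
        dup = pairs.loc[pairs["pair_name"].duplicated(), "pair_name"].iloc[0]
        raise ValidationError(f"duplicate pair_name: {dup!r}")
    return pairs.copy()


@dataclass
class Embedding:
    """Low-dimensional unit coordinates; row order equals count-matrix unit order."""

    coords: np.ndarray  # units x d
    method: str
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValidationError("embedding must be 2-D (units x d)")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("embedding contains non-finite values")
        if self.unit_ids and len(self.unit_ids) != self.coords.shape[0]:
            raise ValidationError("unit ids do not match embedding rows")

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class KNNGraph:
    """Symmetrized k-nearest-neighbour graph as per-unit neighbour index lists."""

    neighbors: list[np.ndarray]
    k: int
    symmetrized: bool = True
    unit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, nb in enumerate(self.neighbors):
            nb = np.asarray(nb, dtype=int)
            if np.any(nb == i):
                raise ValidationError(f"self-loop at unit {i}")
            self.neighbors[i] = nb

    @property
    def n_units(self) -> int:
        return len(self.neighbors)

    def is_symmetric(self) -> bool:
        sets = [set(nb.tolist()) for nb in self.neighbors]
        return all(i in sets[j] for i, s in enumerate(sets) for j in s)
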