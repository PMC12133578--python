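"""Readers and writers for the on-disk formats used by the pipeline.

Formats: Matrix Market triplets with sidecar gene/barcode name files (or a
dense TSV for small fixtures), annotation TSV, AIRR-C rearrangement TSV,
GMT gene sets, receptor-ligand TSV, spot coordinate TSV, and generic
edge-list TSV for networks. Readers never reorder: output id order equals
input file order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .datamodel import (
    CountMatrix,
    FormatError,
    GeneSet,
    SpatialDataset,
    ValidationError,
    validate_annotation,
    validate_clonotypes,
    validate_rl_pairs,
)

log = logging.getLogger("mucosa")


# ---------------------------------------------------------------------------
# counts

def read_counts(
    matrix_path: str | Path,
    genes_path: str | Path | None = None,
    units_path: str | Path | None = None,
) -> CountMatrix:
    """Read a count matrix.

    Either a Matrix Market coordinate file plus row (gene) and column (unit)
    name files, or — when ``genes_path``/``units_path`` are omitted — a dense
    TSV whose header row holds unit ids and first column holds gene ids.
    """
    matrix_path = Path(matrix_path)
    if genes_path is None and units_path is None:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        values = df.to_numpy()
        if np.any(values < 0):
            raise ValidationError("negative count entries present")
        return CountMatrix(sp.csr_matrix(values), list(df.index.astype(str)),
                           list(df.columns.astype(str)))
    if genes_path is None or units_path is None:
        raise FormatError("triplet format requires both gene and unit name files")
    mat = scipy.io.mmread(matrix_path)
    genes = _read_names(genes_path)
    units = _read_names(units_path)
    if mat.shape != (len(genes), len(units)):
        raise FormatError(
            f"matrix is {mat.shape} but name files declare "
            f"{len(genes)} genes x {len(units)} units"
        )
    return CountMatrix(sp.csr_matrix(mat), genes, units)


def write_counts(counts: CountMatrix, matrix_path: str | Path,
                 genes_path: str | Path, units_path: str | Path) -> None:
    scipy.io.mmwrite(str(matrix_path), counts.values.tocoo(), field="integer")
    _write_names(counts.gene_ids, genes_path)
    _write_names(counts.unit_ids, units_path)


def _read_names(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _write_names(names: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for n in names:
            fh.write(f"{n}\n")


# ---------------------------------------------------------------------------
# annotation

def read_annotation(path: str | Path, counts: Optional[CountMatrix] = None) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(ann, counts)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clonotypes (AIRR-C rearrangement dialect)

_AIRR_ALIASES = {
    "repertoire_id": "sample_id",
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "duplicate_count": "count",
}


def read_clonotypes(path: str | Path,
                    segment_vocabulary: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read an AIRR-C rearrangement TSV into a clonotype table.

    ``duplicate_count`` defaults to 1 when missing. V calls outside
    ``segment_vocabulary`` are retained and flagged (``v_call_known`` False),
    with a warning, rather than dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns=_AIRR_ALIASES)
    for col in ("sample_id", "v_call", "j_call", "cdr3_aa"):
        if col not in df.columns:
            raise FormatError(f"rearrangement file missing mandatory column {col!r}")
    if "count" not in df.columns:
        df["count"] = 1
    df["count"] = df["count"].fillna(1).astype(int)
    table = validate_clonotypes(df)
    if segment_vocabulary is not None:
        vocab = set(segment_vocabulary)
        known = table["v_call"].isin(vocab)
        table["v_call_known"] = known
        n_bad = int((~known).sum())
        if n_bad:
            examples = sorted(set(table.loc[~known, "v_call"]))[:5]
            log.warning("%d rows with v_call outside vocabulary (e.g. %s); retained and flagged",
                        n_bad, examples)
    return table


def write_clonotypes(table: pd.DataFrame, path: str | Path) -> None:
    out = table.rename(columns={v: k for k, v in _AIRR_ALIASES.items()})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spatial

def read_spatial(matrix_path: str | Path, genes_path: str | Path | None,
                 units_path: str | Path | None, coords_path: str | Path,
                 lattice: str) -> SpatialDataset:
    """Read spot counts plus a coordinates TSV (spot_id, array_row, array_col)."""
    counts = read_counts(matrix_path, genes_path, units_path)
    coords = pd.read_csv(coords_path, sep="\t", dtype={"spot_id": str})
    for col in ("spot_id", "array_row", "array_col"):
        if col not in coords.columns:
            raise FormatError(f"coordinates file missing column {col!r}")
    missing = set(coords["spot_id"]) - set(counts.unit_ids)
    if missing:
        raise ValidationError(f"spots absent from counts: {sorted(missing)[:5]}")
    coords = coords.set_index("spot_id").loc[counts.unit_ids]
    region = None
    if "region" in coords.columns and coords["region"].notna().all():
        region = list(coords["region"].astype(str))
    return SpatialDataset(
        spots=list(counts.unit_ids), lattice=lattice,
        array_row=coords["array_row"].to_numpy(int),
        array_col=coords["array_col"].to_numpy(int),
        counts=counts, region=region,
    )


def write_spatial(spatial: SpatialDataset, matrix_path: str | Path,
                  genes_path: str | Path, units_path: str | Path,
                  coords_path: str | Path) -> None:
    write_counts(spatial.counts, matrix_path, genes_path, units_path)
    df = pd.DataFrame({
        "spot_id": spatial.spots,
        "array_row": spatial.array_row,
        "array_col": spatial.array_col,
    })
    if spatial.region is not None:
        df["region"] = spatial.region
    df.to_csv(coords_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets / receptor-ligand pairs

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets.append(GeneSet(name, frozenset(g for g in genes if g)))
    if not sets:
        raise FormatError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na"] + sorted(s.genes)) + "\n")


def read_rl_pairs(path: str | Path) -> pd.DataFrame:
    return validate_rl_pairs(pd.read_csv(path, sep="\t", dtype=str))


# ---------------------------------------------------------------------------
# generic outputs

def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    """Write a network as (source, target, weight) TSV."""
    edges.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# config + logging

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config must be a mapping")
    return cfg


def log_run(command: str, config: dict, seed: Optional[int]) -> None:
    """Log the resolved configuration and seed for a CLI run."""
    log.info("command=%s seed=%s config=%s", command, seed,
             yaml.safe_dump(config, default_flow_style=True).strip())
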