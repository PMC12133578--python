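"""Synthetic single-cell, repertoire and spatial datasets with known ground truth.

The generators are pure functions of (config, seed): identical configs give
byte-identical outputs. They emulate the statistical structure the analysis
modules assume — negative-binomial counts with cell-type marker blocks and
condition-dependent abundance, clonotype tables with condition-biased V-segment
usage and power-law clonal expansion, and lattice datasets with banded regions
plus focal circular aggregates mixing cell-type signatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import AA_ALPHABET, CONDITIONS, CountMatrix, SpatialDataset


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """Per-unit generator truth, aligned one-to-one with the generated data."""

    cell_types: Optional[pd.Series] = None          # unit_id -> true type
    marker_genes: Optional[dict[str, list[str]]] = None
    total_counts: Optional[int] = None
    clonotype_v: Optional[pd.Series] = None         # row index -> true V segment
    clonotype_public: Optional[pd.Series] = None    # row index -> from shared pool
    spot_region: Optional[pd.Series] = None         # spot_id -> true region
    spot_composition: Optional[pd.DataFrame] = None  # spot_id x type

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a single TSV-serializable table (one row per unit)."""
        if self.cell_types is not None:
            df = pd.DataFrame({"unit_id": self.cell_types.index,
                               "true_type": self.cell_types.values})
            return df
        if self.clonotype_v is not None:
            return pd.DataFrame({"true_v": self.clonotype_v.values,
                                 "public": self.clonotype_public.values})
        if self.spot_region is not None:
            df = self.spot_composition.copy()
            df.insert(0, "true_region", self.spot_region)
            return df.reset_index(names="spot_id")
        raise ValueError("empty ground truth")


# ---------------------------------------------------------------------------
# negative-binomial sampling helper

def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float | None) -> np.ndarray:
    """NB(mean, size=dispersion); Poisson limit when dispersion is None/inf."""
    mean = np.maximum(mean, 1e-12)
    if dispersion is None or not np.isfinite(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


# ---------------------------------------------------------------------------
# cells

@dataclass
class CellSimConfig:
    n_types: int = 3
    n_genes: int = 200
    cells_per_sample: int = 250
    samples_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 3, "ACD": 3})
    base_mean: float = 0.5
    marker_logfc: float = 3.0
    abundance_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)
    dispersion: float = 2.0
    depth_variation: float = 0.25
    markers_per_type: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ConfigError("marker blocks exceed n_genes")
        for k in self.samples_per_condition:
            if k not in CONDITIONS:
                raise ConfigError(f"unknown condition {k!r}")
        for (_t, c), f in self.abundance_shift.items():
            if f <= 0:
                raise ConfigError("abundance factors must be > 0")

    @property
    def type_names(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_types)]

    def type_probs(self, condition: str) -> np.ndarray:
        w = np.ones(self.n_types)
        for i, t in enumerate(self.type_names):
            w[i] *= self.abundance_shift.get((t, condition), 1.0)
        return w / w.sum()


def simulate_cells(config: CellSimConfig) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a multi-sample, multi-condition single-cell count matrix.

    Per gene, counts follow a negative binomial whose mean carries a
    ``2**marker_logfc`` elevation inside each type's marker block; per-cell
    sequencing depth is a shared log-normal multiplier. The annotation's
    ``cluster`` column is left empty (filled later by clustering).
    """
    rng = np.random.default_rng(config.seed)
    types = config.type_names
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    m = config.markers_per_type
    marker_genes = {t: gene_ids[i * m:(i + 1) * m] for i, t in enumerate(types)}

    # mean expression per (gene, type)
    mu = np.full((config.n_genes, config.n_types), config.base_mean)
    for i in range(config.n_types):
        mu[i * m:(i + 1) * m, i] *= 2.0 ** config.marker_logfc

    unit_ids: list[str] = []
    sample_col: list[str] = []
    cond_col: list[str] = []
    type_col: list[str] = []
    blocks: list[sp.csr_matrix] = []
    total = 0

    for cond in CONDITIONS:
        n_samples = config.samples_per_condition.get(cond, 0)
        probs = config.type_probs(cond)
        for s in range(n_samples):
            sample_id = f"{cond}{s + 1}"
            t_idx = rng.choice(config.n_types, size=config.cells_per_sample, p=probs)
            depth = rng.lognormal(0.0, config.depth_variation,
                                  size=config.cells_per_sample)
            means = mu[:, t_idx] * depth[None, :]
            counts = _nb_sample(rng, means, config.dispersion)
            total += int(counts.sum())
            blocks.append(sp.csr_matrix(counts))
            for j in range(config.cells_per_sample):
                unit_ids.append(f"{sample_id}_c{j:05d}")
            sample_col += [sample_id] * config.cells_per_sample
            cond_col += [cond] * config.cells_per_sample
            type_col += [types[i] for i in t_idx]

    values = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((config.n_genes, 0))
    counts_cm = CountMatrix(values, gene_ids, unit_ids)
    annotation = pd.DataFrame({
        "unit_id": unit_ids, "sample_id": sample_col,
        "condition": cond_col, "cluster": pd.NA,
    })
    truth = GroundTruth(
        cell_types=pd.Series(type_col, index=unit_ids, name="true_type"),
        marker_genes=marker_genes, total_counts=total,
    )
    return counts_cm, annotation, truth


# ---------------------------------------------------------------------------
# repertoire

# standard genetic code, amino acid -> codons (stop codons excluded)
_BASES = "TCAG"
_AA_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODONS_BY_AA: dict[str, list[str]] = {}
for _i, _aa in enumerate(_AA_TABLE):
    if _aa == "*":
        continue
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)


@dataclass
class RepertoireSimConfig:
    v_vocabulary: Sequence[str] = field(
        default_factory=lambda: [f"TRBV{i}" for i in range(1, 11)])
    j_vocabulary: Sequence[str] = field(
        default_factory=lambda: [f"TRBJ{i}" for i in range(1, 5)])
    v_probs: Mapping[str, Sequence[float]] = field(default_factory=dict)
    n_clones: int = 2000
    expansion_shape: float = 2.5
    cdr3_core_length: tuple[int, int] = (6, 12)
    samples_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 3, "ACD": 3})
    public_pool_fraction: float = 0.0
    seed: int = 0
    max_clone_size: int = 10_000

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ConfigError("n_clones must be >= 1")
        nv = len(self.v_vocabulary)
        for cond, p in self.v_probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (nv,):
                raise ConfigError(
                    f"v_probs[{cond}] has length {p.size}, vocabulary has {nv}")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ConfigError(f"v_probs[{cond}] does not sum to 1")

    def probs_for(self, condition: str) -> np.ndarray:
        if condition in self.v_probs:
            return np.asarray(self.v_probs[condition], dtype=float)
        n = len(self.v_vocabulary)
        return np.full(n, 1.0 / n)


def _random_cdr3(rng: np.random.Generator, n: int,
                 core_length: tuple[int, int]) -> tuple[list[str], list[str]]:
    """Germline-framed CDR3s: aa = 'CAS' + core + 'F'; nt codon-wise consistent."""
    lo, hi = core_length
    lengths = rng.integers(lo, hi + 1, size=n)
    aa_out, nt_out = [], []
    for L in lengths:
        core_idx = rng.integers(0, len(AA_ALPHABET), size=L)
        aa = "CAS" + "".join(AA_ALPHABET[i] for i in core_idx) + "F"
        nt = "".join(
            CODONS_BY_AA[a][rng.integers(0, len(CODONS_BY_AA[a]))] for a in aa)
        aa_out.append(aa)
        nt_out.append(nt)
    return aa_out, nt_out


def _draw_clonotypes(rng: np.random.Generator, n: int, cfg: RepertoireSimConfig,
                     v_probs: np.ndarray) -> pd.DataFrame:
    v_idx = rng.choice(len(cfg.v_vocabulary), size=n, p=v_probs)
    j_idx = rng.integers(0, len(cfg.j_vocabulary), size=n)
    aa, nt = _random_cdr3(rng, n, cfg.cdr3_core_length)
    return pd.DataFrame({
        "v_call": [cfg.v_vocabulary[i] for i in v_idx],
        "j_call": [cfg.j_vocabulary[i] for i in j_idx],
        "cdr3_nt": nt, "cdr3_aa": aa,
    })


def simulate_repertoire(config: RepertoireSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw clonotype tables with condition-biased V usage and clonal expansion.

    Per sample: ``n_clones`` unique clonotypes with V drawn from the
    condition's segment probabilities, J uniform, and CDR3 = germline prefix +
    random core + germline suffix. Clone sizes are zeta-distributed (shape =
    ``expansion_shape``, truncated at ``max_clone_size``). A
    ``public_pool_fraction`` of clonotypes is reused from a condition-shared
    pool, producing inter-sample sequence sharing.
    """
    rng = np.random.default_rng(config.seed)
    pools: dict[str, pd.DataFrame] = {}
    rows: list[pd.DataFrame] = []
    truth_v: list[str] = []
    truth_public: list[bool] = []

    for cond in CONDITIONS:
        n_samples = config.samples_per_condition.get(cond, 0)
        if n_samples == 0:
            continue
        v_probs = config.probs_for(cond)
        if config.public_pool_fraction > 0:
            pools[cond] = _draw_clonotypes(rng, config.n_clones, config, v_probs)
        for s in range(n_samples):
            sample_id = f"{cond}{s + 1}"
            n_public = int(rng.binomial(config.n_clones, config.public_pool_fraction))
            parts = []
            public_flags = np.zeros(config.n_clones, dtype=bool)
            if n_public > 0:
                take = rng.choice(len(pools[cond]), size=n_public, replace=False)
                parts.append(pools[cond].iloc[np.sort(take)].reset_index(drop=True))
                public_flags[:n_public] = True
            n_private = config.n_clones - n_public
            if n_private > 0:
                priv = _draw_clonotypes(rng, n_private, config, v_probs)
                parts.append(priv)
            clones = pd.concat(parts, ignore_index=True)
            clones = clones.drop_duplicates(subset=["v_call", "cdr3_nt"], keep="first")
            public_flags = public_flags[: len(clones)]
            sizes = np.minimum(rng.zipf(config.expansion_shape, size=len(clones)),
                               config.max_clone_size)
            clones.insert(0, "sample_id", sample_id)
            clones.insert(1, "condition", cond)
            clones["count"] = sizes
            rows.append(clones)
            truth_v += list(clones["v_call"])
            truth_public += list(public_flags)

    table = pd.concat(rows, ignore_index=True)
    table["cluster"] = pd.NA
    truth = GroundTruth(
        clonotype_v=pd.Series(truth_v, name="true_v"),
        clonotype_public=pd.Series(truth_public, name="public"),
    )
    return table, truth


# ---------------------------------------------------------------------------
# spatial

@dataclass
class SpatialSimConfig:
    lattice: str = "hex"
    n_rows: int = 30
    n_cols: int = 30
    # bands: {"region": name, "row_start": int, "row_stop": int} (half-open)
    # circles: {"region": name, "center": (row, col), "radius": float}
    region_layout: Sequence[Mapping] = field(default_factory=list)
    composition: Mapping[str, Sequence[float]] = field(default_factory=dict)
    signatures: Optional[pd.DataFrame] = None  # genes x types, non-negative means
    noise_dispersion: Optional[float] = 10.0   # None => Poisson limit
    depth: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for region, comp in self.composition.items():
            comp = np.asarray(comp, dtype=float)
            if abs(comp.sum() - 1.0) > 1e-9:
                raise ConfigError(f"composition[{region}] does not sum to 1")


def default_signatures(n_genes: int = 60, types: Sequence[str] = ("epithelial", "immune", "stromal"),
                       markers_per_type: int = 10, base: float = 1.0,
                       marker_level: float = 10.0) -> pd.DataFrame:
    """Block-structured genes x types mean matrix for spatial simulations."""
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    S = np.full((n_genes, len(types)), base)
    for i in range(len(types)):
        S[i * markers_per_type:(i + 1) * markers_per_type, i] = marker_level
    return pd.DataFrame(S, index=gene_ids, columns=list(types))


def _lattice_xy(lattice: str, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geometric coordinates; odd-row-shifted hex offsets odd rows half a column."""
    if lattice == "hex":
        x = cols + 0.5 * (rows % 2)
        y = rows * (math.sqrt(3.0) / 2.0)
    else:
        x = cols.astype(float)
        y = rows.astype(float)
    return x, y


def assign_regions(config: SpatialSimConfig,
                   rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Resolve the layered region layout; circles override bands."""
    region = np.array([None] * len(rows), dtype=object)
    for item in config.region_layout:
        if "row_start" in item:
            mask = (rows >= item["row_start"]) & (rows < item["row_stop"])
            region[mask] = item["region"]
    x, y = _lattice_xy(config.lattice, rows, cols)
    for item in config.region_layout:
        if "center" in item:
            cr, cc = item["center"]
            cx, cy = _lattice_xy(config.lattice, np.array([cr]), np.array([cc]))
            mask = (x - cx[0]) ** 2 + (y - cy[0]) ** 2 <= item["radius"] ** 2
            region[mask] = item["region"]
    if any(r is None for r in region):
        i = next(i for i, r in enumerate(region) if r is None)
        raise ConfigError(
            f"region_layout leaves lattice position ({rows[i]}, {cols[i]}) uncovered")
    return region.astype(str)


def simulate_spatial(config: SpatialSimConfig) -> tuple[SpatialDataset, GroundTruth]:
    """Draw a lattice dataset whose spots mix cell-type signatures by region.

    Per spot, the expected expression is ``signatures @ composition[region]``
    rescaled to ``depth`` total counts, with negative-binomial noise
    (Poisson in the ``noise_dispersion=None`` limit).
    """
    if config.signatures is None:
        config.signatures = default_signatures()
    S = config.signatures.to_numpy(dtype=float)
    types = list(config.signatures.columns)
    gene_ids = list(config.signatures.index)
    for region, comp in config.composition.items():
        if len(comp) != len(types):
            raise ConfigError(f"composition[{region}] length != number of types")

    rng = np.random.default_rng(config.seed)
    rr, cc = np.meshgrid(np.arange(config.n_rows), np.arange(config.n_cols),
                         indexing="ij")
    rows, cols = rr.ravel(), cc.ravel()
    region = assign_regions(config, rows, cols)
    missing = set(region) - set(config.composition)
    if missing:
        raise ConfigError(f"regions without composition: {sorted(missing)}")

    spot_ids = [f"s{r:03d}x{c:03d}" for r, c in zip(rows, cols)]
    comp_matrix = np.stack([np.asarray(config.composition[r], dtype=float)
                            for r in region])  # spots x types
    mean = S @ comp_matrix.T  # genes x spots
    mean = mean * (config.depth / mean.sum(axis=0, keepdims=True))
    counts = _nb_sample(rng, mean, config.noise_dispersion)

    cm = CountMatrix(sp.csr_matrix(counts), gene_ids, spot_ids)
    ds = SpatialDataset(spots=spot_ids, lattice=config.lattice,
                        array_row=rows, array_col=cols, counts=cm,
                        region=None)
    truth = GroundTruth(
        spot_region=pd.Series(region, index=spot_ids, name="true_region"),
        spot_composition=pd.DataFrame(comp_matrix, index=spot_ids, columns=types),
    )
    return ds, truth
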