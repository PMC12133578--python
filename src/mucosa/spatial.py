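"""Spot-level region analysis: lattice neighbors, region clustering,
composition, adjacency networks, signature deconvolution, colocalization,
region markers and region gene-set enrichment."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datamodel import CountMatrix, GeneSet, SpatialDataset
from . import preprocess

log = logging.getLogger("mucosa")


# ---------------------------------------------------------------------------
# lattice geometry

def neighbors(spatial: SpatialDataset) -> list[np.ndarray]:
    """Per-spot neighbor index lists.

    Square lattices use the 4-neighborhood; hex lattices the odd-row-shifted
    (Visium-style) 6-neighborhood, where odd array rows sit half a column to
    the right. Boundary spots simply have fewer neighbors.
    """
    pos = {(int(r), int(c)): i
           for i, (r, c) in enumerate(zip(spatial.array_row, spatial.array_col))}
    out = []
    for r, c in zip(spatial.array_row, spatial.array_col):
        r, c = int(r), int(c)
        if spatial.lattice == "square":
            cand = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
        else:
            shift = 1 if r % 2 else -1
            cand = [(r, c - 1), (r, c + 1), (r - 1, c), (r + 1, c),
                    (r - 1, c + shift), (r + 1, c + shift)]
        out.append(np.array(sorted(pos[p] for p in cand if p in pos), dtype=int))
    return out


# ---------------------------------------------------------------------------
# regions

def cluster_spots(spatial: SpatialDataset, n_hvg: int = 50, n_pcs: int = 10,
                  k: int = 15, resolution: float = 0.3, seed: int = 0) -> list[str]:
    """Transcriptome-driven region labels via the shared preprocessing stack
    (normalize -> HVG -> scale -> PCA -> KNN -> Leiden)."""
    norm = preprocess.normalize_log(spatial.counts)
    if norm.excluded_units:
        raise ValueError(f"zero-count spots present: {norm.excluded_units[:5]}")
    hvg = preprocess.select_hvg(norm, min(n_hvg, norm.n_genes))
    idx = [norm.gene_ids.index(g) for g in hvg]
    sub = preprocess.NormalizedMatrix(
        values=norm.values[idx, :], gene_ids=hvg, unit_ids=norm.unit_ids,
        target_sum=norm.target_sum, excluded_units=[])
    scaled = preprocess.scale_genes(sub)
    emb = preprocess.pca_embed(scaled, n_pcs, unit_ids=norm.unit_ids, seed=seed)
    knn = preprocess.build_knn(emb, k=min(k, emb.coords.shape[0] - 1))
    labels = preprocess.cluster_graph(knn, resolution=resolution, seed=seed)
    log.info("cluster_spots found %d regions", len(set(labels)))
    return [f"R{l[1:]}" for l in labels]


def region_proportions(assignments: pd.DataFrame,
                       condition_of: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Per-sample region fractions from a (sample_id, region) table, with
    optional per-condition mean summaries attached."""
    rows = []
    for sample, grp in assignments.groupby("sample_id", sort=True):
        fracs = grp["region"].value_counts(normalize=True)
        for region, f in fracs.sort_index().items():
            rows.append({"sample_id": sample, "region": region,
                         "fraction": float(f),
                         "n_spots": int((grp["region"] == region).sum())})
    out = pd.DataFrame(rows)
    if condition_of is not None:
        out["condition"] = out["sample_id"].map(condition_of)
    return out


@dataclass
class RegionAdjacencyNetwork:
    """Row-stochastic region x region neighbor-pair fractions."""

    regions: list[str]
    P: pd.DataFrame            # rows sum to 1 (missing rows all-NaN)
    edges: pd.DataFrame        # (source, target, weight), self-pairs excluded


def region_adjacency(spatial: SpatialDataset,
                     region: Optional[Sequence[str]] = None) -> RegionAdjacencyNetwork:
    """Fraction of ordered neighbor pairs (i in r, j in s) among all ordered
    neighbor pairs with i in r. Self-adjacency is retained in the matrix but
    excluded from the edge list. Regions whose spots have no neighbors get an
    all-missing row (reported)."""
    region = list(region if region is not None else spatial.region)
    if region is None:
        raise ValueError("regions not assigned")
    nbrs = neighbors(spatial)
    labels = sorted(set(region))
    idx = {r: i for i, r in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)))
    for i, nb in enumerate(nbrs):
        for j in nb:
            M[idx[region[i]], idx[region[j]]] += 1.0
    row_sums = M.sum(axis=1)
    P = np.full_like(M, np.nan)
    ok = row_sums > 0
    P[ok] = M[ok] / row_sums[ok, None]
    for r, good in zip(labels, ok):
        if not good:
            log.warning("region %s has no incident neighbor pairs; row missing", r)
    Pdf = pd.DataFrame(P, index=labels, columns=labels)
    edges = [{"source": r, "target": s, "weight": Pdf.loc[r, s]}
             for r in labels for s in labels
             if r != s and np.isfinite(Pdf.loc[r, s]) and Pdf.loc[r, s] > 0]
    return RegionAdjacencyNetwork(regions=labels, P=Pdf,
                                  edges=pd.DataFrame(edges))


# ---------------------------------------------------------------------------
# deconvolution

def build_signatures(counts: CountMatrix, annotation: pd.DataFrame,
                     genes: Optional[Sequence[str]] = None,
                     target_sum: float = 10_000.0,
                     min_cells: int = 10) -> pd.DataFrame:
    """Mean library-size-normalized expression per cell type (genes x types)."""
    norm = preprocess.normalize_log(counts, target_sum=target_sum)
    linear = norm.linear
    cluster = annotation.set_index("unit_id")["cluster"].reindex(norm.unit_ids)
    types = sorted(cluster.dropna().unique())
    cols = {}
    for t in types:
        mask = (cluster == t).to_numpy()
        if mask.sum() < min_cells:
            log.warning("type %s has only %d cells", t, int(mask.sum()))
        cols[t] = np.asarray(linear[:, mask].mean(axis=1)).ravel()
    S = pd.DataFrame(cols, index=norm.gene_ids)
    if genes is not None:
        S = S.loc[[g for g in genes if g in S.index]]
    return S


@dataclass
class DeconvolutionResult:
    weights: pd.DataFrame       # spots x types, rows on the simplex
    residual: pd.Series         # per-spot NNLS residual norm
    signatures: pd.DataFrame    # genes x types actually used
    region_means: Optional[pd.DataFrame] = None  # region x types


def deconvolve(spatial: SpatialDataset, signatures: pd.DataFrame,
               target_sum: float = 10_000.0,
               region: Optional[Sequence[str]] = None) -> DeconvolutionResult:
    """Non-negative least squares of each normalized spot on the signature
    matrix; weights renormalized to the simplex."""
    shared = [g for g in signatures.index if g in set(spatial.counts.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between signatures and spot matrix")
    if signatures.shape[1] > len(shared):
        raise ValueError("more cell types than shared genes")
    S = signatures.loc[shared].to_numpy(dtype=float)
    counts = spatial.counts.subset_genes(shared)
    totals = counts.unit_totals().astype(float)
    totals[totals == 0] = 1.0
    B = counts.values.toarray() * (target_sum / totals[None, :])
    W = np.zeros((spatial.n_spots, signatures.shape[1]))
    resid = np.zeros(spatial.n_spots)
    for j in range(spatial.n_spots):
        w, r = nnls(S, B[:, j])
        s = w.sum()
        W[j] = w / s if s > 0 else 1.0 / len(w)
        resid[j] = r
    weights = pd.DataFrame(W, index=spatial.spots, columns=signatures.columns)
    region = region if region is not None else spatial.region
    region_means = None
    if region is not None:
        region_means = weights.groupby(pd.Series(list(region),
                                                 index=weights.index)).mean()
    return DeconvolutionResult(weights=weights,
                               residual=pd.Series(resid, index=spatial.spots),
                               signatures=signatures.loc[shared],
                               region_means=region_means)


@dataclass
class ColocalizationNetwork:
    correlation: pd.DataFrame   # type x type, symmetric, unit diagonal
    edges: pd.DataFrame         # pairs with correlation >= threshold


def colocalization(deconv: DeconvolutionResult, method: str = "spearman",
                   threshold: float = 0.3) -> ColocalizationNetwork:
    """Pairwise correlation of deconvolved type proportions across spots.

    Constant proportion vectors yield missing correlations for that type.
    """
    W = deconv.weights
    if len(W) < 10:
        raise ValueError("need at least 10 spots for colocalization")
    corr = W.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    types = list(corr.columns)
    edges = [{"source": a, "target": b, "weight": float(corr.loc[a, b])}
             for i, a in enumerate(types) for b in types[i + 1:]
             if np.isfinite(corr.loc[a, b]) and corr.loc[a, b] >= threshold]
    return ColocalizationNetwork(correlation=corr, edges=pd.DataFrame(edges))


# ---------------------------------------------------------------------------
# markers + gene-set enrichment

def region_markers(spatial: SpatialDataset, region_label: str,
                   region: Optional[Sequence[str]] = None,
                   min_spots: int = 20) -> pd.DataFrame:
    """Rank-sum region-vs-rest marker test per gene with log2 fold change of
    normalized means and BH correction."""
    region = list(region if region is not None else spatial.region)
    mask = np.array([r == region_label for r in region])
    if mask.sum() < min_spots:
        raise ValueError(
            f"region {region_label!r} has {int(mask.sum())} < {min_spots} spots")
    norm = preprocess.normalize_log(spatial.counts)
    X = np.asarray(norm.values.todense())
    inside, outside = X[:, mask], X[:, ~mask]
    res = mannwhitneyu(inside, outside, axis=1, alternative="two-sided",
                       method="asymptotic")
    lin = np.asarray(norm.linear.todense())
    eps = 1e-9
    lfc = np.log2((lin[:, mask].mean(axis=1) + eps) /
                  (lin[:, ~mask].mean(axis=1) + eps))
    p = np.asarray(res.pvalue, dtype=float)
    constant = X.std(axis=1) == 0
    p[constant] = 1.0
    lfc[constant] = 0.0
    out = pd.DataFrame({"gene": norm.gene_ids, "lfc": lfc, "p": p})
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["q", "p", "gene"]).reset_index(drop=True)


def set_enrichment_by_group(scaled: np.ndarray, gene_ids: Sequence[str],
                            group_labels: Sequence[str], gene_set: GeneSet,
                            normalized_mean: Optional[np.ndarray] = None,
                            n_perm: int = 999, n_bins: int = 10,
                            seed: int = 0) -> pd.DataFrame:
    """Permutation gene-set score per group of units (regions or cell types).

    Observed score per group = mean scaled expression of the set genes over
    the group's units. The null re-draws gene sets of equal size from
    expression-matched (decile) bins; z is the null-standardized score and
    p = (1 + #null >= obs) / (1 + n_perm), BH-corrected across groups.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    sig_idx = sorted(index[g] for g in gene_set.genes if g in index)
    if not sig_idx:
        raise ValueError(f"no gene of set {gene_set.name!r} present")
    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    if normalized_mean is None:
        normalized_mean = scaled.mean(axis=1)
    ranks = pd.Series(normalized_mean).rank(method="first").to_numpy()
    bins = np.minimum((ranks - 1) * n_bins // n_genes, n_bins - 1).astype(int)
    # matched background excludes the signature itself; empty bins fall back
    # to the whole non-signature gene pool
    non_sig = np.setdiff1d(np.arange(n_genes), sig_idx)
    pools = {}
    for b in range(n_bins):
        pool = np.flatnonzero(bins == b)
        pool = pool[~np.isin(pool, sig_idx)]
        pools[b] = pool if pool.size else non_sig

    labels = np.asarray([str(g) for g in group_labels])
    groups = sorted(set(labels))
    # per-gene per-group mean of scaled expression
    G = np.stack([scaled[:, labels == g].mean(axis=1) for g in groups], axis=1)
    obs = G[sig_idx].mean(axis=0)

    draws = np.empty((len(sig_idx), n_perm), dtype=int)
    for r, i in enumerate(sig_idx):
        draws[r] = rng.choice(pools[bins[i]], size=n_perm)
    null = G[draws].mean(axis=0)  # n_perm x groups
    mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = (obs - mu) / sd
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (1 + n_perm)
    out = pd.DataFrame({"group": groups, "score": obs, "z": z, "p": p})
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def region_set_enrichment(spatial: SpatialDataset, gene_set: GeneSet,
                          region: Optional[Sequence[str]] = None,
                          n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Expression-matched permutation enrichment of a gene set per region."""
    region = list(region if region is not None else spatial.region)
    norm = preprocess.normalize_log(spatial.counts)
    scaled = preprocess.scale_genes(norm)
    mean = np.asarray(norm.values.mean(axis=1)).ravel()
    out = set_enrichment_by_group(scaled, norm.gene_ids, region, gene_set,
                                  normalized_mean=mean, n_perm=n_perm, seed=seed)
    return out.rename(columns={"group": "region"})
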