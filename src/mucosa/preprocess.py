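"""Normalization, feature selection, embedding, graph construction, clustering
and gene-signature scoring shared by the single-cell and spot analyses."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datamodel import CountMatrix, Embedding, GeneSet, KNNGraph

log = logging.getLogger("mucosa")


@dataclass
class NormalizedMatrix:
    """Library-size normalized, log1p-transformed expression (genes x units)."""

    values: sp.csr_matrix
    gene_ids: list[str]
    unit_ids: list[str]
    target_sum: float
    excluded_units: list[str]
    linear: Optional[sp.csr_matrix] = None  # pre-log values, same scale

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


def normalize_log(counts: CountMatrix, target_sum: float = 10_000.0) -> NormalizedMatrix:
    """Scale each unit to ``target_sum`` total counts, then log(1 + x).

    Units with zero total counts are excluded (with a warning); their ids are
    reported on the result.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be > 0")
    totals = counts.unit_totals()
    keep = totals > 0
    excluded = [u for u, k in zip(counts.unit_ids, keep) if not k]
    if excluded:
        log.warning("excluding %d zero-count units", len(excluded))
    mat = counts.values[:, keep].astype(float)
    scale = target_sum / totals[keep]
    linear = mat @ sp.diags(scale)
    values = linear.copy()
    values.data = np.log1p(values.data)
    return NormalizedMatrix(
        values=sp.csr_matrix(values), gene_ids=list(counts.gene_ids),
        unit_ids=[u for u, k in zip(counts.unit_ids, keep) if k],
        target_sum=target_sum, excluded_units=excluded,
        linear=sp.csr_matrix(linear),
    )


def scale_genes(normalized: NormalizedMatrix, clip: float = 10.0) -> np.ndarray:
    """Z-score each gene across units (dense genes x units), clipped at ±clip.

    Constant genes are set to 0.
    """
    X = np.asarray(normalized.values.todense())
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant genes -> 0
    Z = (X - mean) / sd
    np.clip(Z, -clip, clip, out=Z)
    return Z


def select_hvg(normalized: NormalizedMatrix, n_top: int) -> list[str]:
    """Top ``n_top`` genes by variance of log-normalized expression.

    Deterministic: ties broken lexicographically by gene id; constant genes
    rank last.
    """
    if n_top > normalized.n_genes:
        raise ValueError("n_top exceeds number of genes")
    X = normalized.values
    mean = np.asarray(X.mean(axis=1)).ravel()
    meansq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = meansq - mean ** 2
    order = sorted(range(len(var)), key=lambda i: (-var[i], normalized.gene_ids[i]))
    return [normalized.gene_ids[i] for i in order[:n_top]]


def pca_embed(scaled: np.ndarray, d: int, unit_ids: Optional[Sequence[str]] = None,
              seed: int = 0) -> Embedding:
    """PCA of the scaled matrix (genes x units) to ``d`` components."""
    X = scaled.T  # units x genes
    d = min(d, min(X.shape) - 1) if min(X.shape) > 1 else 1
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(X)
    # sign convention: largest-|loading| coordinate positive, for determinism
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    return Embedding(coords=coords, method="pca",
                     unit_ids=list(unit_ids) if unit_ids is not None else [])


def build_knn(embedding: Embedding, k: int) -> KNNGraph:
    """Euclidean KNN graph, symmetrized by union; no self-loops."""
    n = embedding.coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of units ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.coords)
    _, idx = nn.kneighbors(embedding.coords)
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in idx[i]:
            if j != i:
                adj[i].add(int(j))
                adj[int(j)].add(i)
    neighbors = [np.array(sorted(s), dtype=int) for s in adj]
    return KNNGraph(neighbors=neighbors, k=k, symmetrized=True,
                    unit_ids=list(embedding.unit_ids))


def cluster_graph(knn: KNNGraph, resolution: float = 0.5, seed: int = 0) -> list[str]:
    """Leiden modularity communities on the KNN graph; deterministic given seed."""
    edges = sorted({(min(i, int(j)), max(i, int(j)))
                    for i, nb in enumerate(knn.neighbors) for j in nb})
    g = igraph.Graph(n=knn.n_units, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    return [f"c{m}" for m in part.membership]


def score_signature(scaled: np.ndarray, gene_ids: Sequence[str], gene_set: GeneSet,
                    normalized_mean: Optional[np.ndarray] = None,
                    background_size: int = 50, n_bins: int = 10,
                    seed: int = 0) -> np.ndarray:
    """Per-unit signature score with an expression-matched background.

    Score = mean scaled expression of the signature genes minus the mean of a
    background set drawn from the same expression deciles (``background_size``
    genes per signature gene). Binning uses the mean expression supplied in
    ``normalized_mean`` (defaults to the mean of the scaled matrix input
    pre-clipping proxy: mean of ``scaled`` rows is ~0, so callers should pass
    the normalized mean; absent that, bins are formed on gene totals of
    ``scaled``).
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    sig_idx = sorted(index[g] for g in gene_set.genes if g in index)
    if not sig_idx:
        raise ValueError(f"no gene of set {gene_set.name!r} present in matrix")
    rng = np.random.default_rng(seed)
    n_genes = len(gene_ids)
    if normalized_mean is None:
        normalized_mean = np.abs(scaled).mean(axis=1)
    # decile bins on mean expression
    ranks = pd.Series(normalized_mean).rank(method="first").to_numpy()
    bins = np.minimum((ranks - 1) * n_bins // n_genes, n_bins - 1).astype(int)
    sig_set = set(sig_idx)
    by_bin: dict[int, np.ndarray] = {}
    for b in range(n_bins):
        pool = np.flatnonzero((bins == b))
        by_bin[b] = pool[~np.isin(pool, list(sig_set))]
    bg_idx: list[int] = []
    for i in sig_idx:
        pool = by_bin[bins[i]]
        if pool.size == 0:
            pool = np.setdiff1d(np.arange(n_genes), list(sig_set))
        take = rng.choice(pool, size=min(background_size, pool.size), replace=False)
        bg_idx.extend(take.tolist())
    sig_score = scaled[sig_idx, :].mean(axis=0)
    bg_score = scaled[sorted(bg_idx), :].mean(axis=0)
    return sig_score - bg_score
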