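"""Receptor-ligand pair scoring between cell types and within spatial regions,
plus susceptibility-gene-set scoring per cell type.

Cell-type pair scores follow the label-permutation scheme: the observed score
for (pair, sender, receiver) is the product of the sender's mean normalized
ligand expression and the receiver's mean normalized receptor expression, and
the null is obtained by shuffling cell-type labels; p-values use the
(1 + #null >= obs) / (1 + n_perm) estimator and are never exactly 0.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datamodel import CountMatrix, GeneSet, SpatialDataset
from . import preprocess
from .spatial import set_enrichment_by_group

log = logging.getLogger("mucosa")


def _group_means(E: np.ndarray, labels: np.ndarray,
                 groups: list[str]) -> np.ndarray:
    """genes x groups mean of E (genes x units) under a label vector."""
    out = np.empty((E.shape[0], len(groups)))
    for k, g in enumerate(groups):
        out[:, k] = E[:, labels == g].mean(axis=1)
    return out


def score_celltype_pairs(counts: CountMatrix, annotation: pd.DataFrame,
                         pairs: pd.DataFrame, n_perm: int = 999,
                         seed: int = 0) -> pd.DataFrame:
    """Permutation-scored receptor-ligand interactions between cell types.

    Pairs whose partner genes are absent from the matrix are skipped and
    reported. BH correction is applied within each pair across sender x
    receiver combinations.
    """
    norm = preprocess.normalize_log(counts)
    ann = annotation.set_index("unit_id")
    labels = ann["cluster"].reindex(norm.unit_ids).astype(str).to_numpy()
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 cell types")
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}

    usable, skipped = [], []
    for row in pairs.itertuples(index=False):
        if row.ligand in gene_pos and row.receptor in gene_pos:
            usable.append(row)
        else:
            skipped.append(row.pair_name)
    if skipped:
        log.warning("pairs skipped (partner gene absent): %s", skipped)
    if not usable:
        return pd.DataFrame(columns=["pair_name", "sender", "receiver", "score",
                                     "lig_detect", "rec_detect", "p", "q"])

    need = sorted({gene_pos[r.ligand] for r in usable} |
                  {gene_pos[r.receptor] for r in usable})
    pos_in_need = {gi: k for k, gi in enumerate(need)}
    E = np.asarray(norm.values[need, :].todense())
    detected = np.asarray((norm.values[need, :] > 0).todense())

    obs_means = _group_means(E, labels, groups)
    det_frac = _group_means(detected.astype(float), labels, groups)

    rng = np.random.default_rng(seed)
    null_means = np.empty((n_perm, len(need), len(groups)))
    for k in range(n_perm):
        null_means[k] = _group_means(E, rng.permutation(labels), groups)

    frames = []
    for row in usable:
        li = pos_in_need[gene_pos[row.ligand]]
        ri = pos_in_need[gene_pos[row.receptor]]
        score = np.outer(obs_means[li], obs_means[ri])          # sender x receiver
        null = null_means[:, li, :][:, :, None] * null_means[:, ri, :][:, None, :]
        p = (1 + (null >= score[None, :, :]).sum(axis=0)) / (1 + n_perm)
        recs = []
        for i, s in enumerate(groups):
            for j, r in enumerate(groups):
                recs.append({
                    "pair_name": row.pair_name, "sender": s, "receiver": r,
                    "score": float(score[i, j]),
                    "lig_detect": float(det_frac[li, i]),
                    "rec_detect": float(det_frac[ri, j]),
                    "p": float(p[i, j]),
                })
        df = pd.DataFrame(recs)
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def score_region_pairs(spatial: SpatialDataset, pairs: pd.DataFrame,
                       region: Optional[Sequence[str]] = None,
                       scheme: str = "min") -> pd.DataFrame:
    """Per-region receptor-ligand coexpression scores.

    ``score`` combines the two partners' mean z-scaled expressions in the
    region (min by default, so a pair scores highly only where both partners
    are expressed; ``product`` alternative). ``score_z`` re-scales the scores
    across regions per pair for bubble-plot display parity. The detection
    fraction counts the region's spots where both partners have count > 0.
    """
    if scheme not in ("min", "product"):
        raise ValueError(f"unknown scheme {scheme!r}")
    region = np.asarray(list(region if region is not None else spatial.region))
    norm = preprocess.normalize_log(spatial.counts)
    scaled = preprocess.scale_genes(norm)
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    regions = sorted(set(region))
    labels = region  # aligned with spots (no zero-count spots expected)
    counts_dense = spatial.counts.values

    rows = []
    for row in pairs.itertuples(index=False):
        if row.ligand not in gene_pos or row.receptor not in gene_pos:
            log.warning("pair %s skipped (partner gene absent)", row.pair_name)
            continue
        li, ri = gene_pos[row.ligand], gene_pos[row.receptor]
        lig_detected = np.asarray((counts_dense[li] > 0).todense()).ravel()
        rec_detected = np.asarray((counts_dense[ri] > 0).todense()).ravel()
        both = lig_detected & rec_detected
        scores = []
        for r in regions:
            m = labels == r
            a = float(scaled[li, m].mean())
            b = float(scaled[ri, m].mean())
            s = min(a, b) if scheme == "min" else a * b
            scores.append((r, s, float(both[m].mean())))
        vals = np.array([s for _, s, _ in scores])
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        zs = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        for (r, s, det), z in zip(scores, zs):
            rows.append({"pair_name": row.pair_name, "region": r,
                         "score": s, "score_z": float(z),
                         "detection_fraction": det})
    return pd.DataFrame(rows)


def celltype_set_score(counts: CountMatrix, annotation: pd.DataFrame,
                       gene_set: GeneSet, n_perm: int = 999,
                       seed: int = 0) -> pd.DataFrame:
    """Expression-matched permutation enrichment of a gene set per cell type."""
    norm = preprocess.normalize_log(counts)
    scaled = preprocess.scale_genes(norm)
    labels = annotation.set_index("unit_id")["cluster"] \
                       .reindex(norm.unit_ids).astype(str).to_numpy()
    mean = np.asarray(norm.values.mean(axis=1)).ravel()
    out = set_enrichment_by_group(scaled, norm.gene_ids, labels, gene_set,
                                  normalized_mean=mean, n_perm=n_perm, seed=seed)
    return out.rename(columns={"group": "cell_type"})
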