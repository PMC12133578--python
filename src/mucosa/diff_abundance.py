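"""Cluster-level proportion tests and KNN-neighborhood differential abundance
between disease states.

The neighborhood test uses closed KNN neighborhoods of sampled index units:
per neighborhood, a pseudocounted log2 fold change of condition membership
odds and a two-sided hypergeometric p-value (doubling rule), with
Benjamini-Hochberg control across neighborhoods. This is a simplified,
fully specified variant of graph-neighborhood differential abundance; it does
not model per-sample replication.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .datamodel import KNNGraph

log = logging.getLogger("mucosa")


def cluster_proportions(annotation: pd.DataFrame,
                        parent_filter: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-sample cluster fractions within a parent compartment.

    ``parent_filter`` restricts the parent compartment to the listed clusters
    (e.g. all T-cell clusters); fractions then sum to 1 over those clusters
    per sample. Samples with zero parent cells are excluded with a warning.
    """
    ann = annotation.dropna(subset=["cluster"])
    if parent_filter is not None:
        ann = ann[ann["cluster"].isin(parent_filter)]
    rows = []
    for (sample, cond), grp in ann.groupby(["sample_id", "condition"], sort=True):
        n_parent = len(grp)
        if n_parent == 0:
            log.warning("sample %s has no parent cells; excluded", sample)
            continue
        counts = grp["cluster"].value_counts()
        for cluster, n in counts.sort_index().items():
            rows.append({
                "sample_id": sample, "condition": cond, "cluster": cluster,
                "n_cells": int(n), "fraction": n / n_parent,
            })
    return pd.DataFrame(rows)


def test_proportions(proportions: pd.DataFrame, group_a: str, group_b: str,
                     bh_correct: bool = False) -> pd.DataFrame:
    """Exact two-sided Mann-Whitney test of per-sample fractions per cluster.

    Samples without cells in a cluster contribute fraction 0. With ties the
    exact test is replaced by the normal approximation with continuity
    correction, flagged in the ``tie_fallback`` column. No cross-cluster
    correction by default (``bh_correct`` adds a BH column).
    """
    for g in (group_a, group_b):
        n = proportions.loc[proportions["condition"] == g, "sample_id"].nunique()
        if n < 2:
            raise ValueError(f"group {g!r} has {n} samples; need >= 2")
    wide = proportions.pivot_table(index=["sample_id", "condition"],
                                   columns="cluster", values="fraction",
                                   fill_value=0.0, aggfunc="first")
    rows = []
    for cluster in sorted(wide.columns):
        xa = wide.xs(group_a, level="condition")[cluster].to_numpy()
        xb = wide.xs(group_b, level="condition")[cluster].to_numpy()
        has_ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
        method = "asymptotic" if has_ties else "exact"
        res = mannwhitneyu(xa, xb, alternative="two-sided", method=method,
                           use_continuity=True)
        rows.append({
            "cluster": cluster, "n_a": len(xa), "n_b": len(xb),
            "median_a": float(np.median(xa)), "median_b": float(np.median(xb)),
            "statistic": float(res.statistic), "p": float(res.pvalue),
            "tie_fallback": has_ties,
        })
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def _hypergeom_two_sided(a: int, n: int, A: int, total: int) -> float:
    """Two-sided hypergeometric p by the doubling rule, capped at 1."""
    lo = hypergeom.cdf(a, total, A, n)
    hi = hypergeom.sf(a - 1, total, A, n)
    return float(min(1.0, 2.0 * min(lo, hi)))


def neighborhood_enrichment(knn: KNNGraph, annotation: pd.DataFrame,
                            conditions: tuple[str, str] = ("ACD", "HC"),
                            n_neighborhoods: Optional[int] = None,
                            min_size: int = 10, pseudocount: float = 0.5,
                            seed: int = 0) -> pd.DataFrame:
    """Differential abundance over closed KNN neighborhoods.

    Index units are sampled uniformly without replacement (default 10% of
    units); each neighborhood is the index unit plus its graph neighbors.
    With a, b the neighborhood counts and A, B the graph-wide totals of the
    two conditions, lfc = log2[(a+p)/(A-a+p)] - log2[(b+p)/(B-b+p)] and the
    p-value is the two-sided hypergeometric tail of a among the a+b members.
    """
    cond_a, cond_b = conditions
    cond = annotation.set_index("unit_id")["condition"]
    if not knn.unit_ids:
        raise ValueError("KNN graph carries no unit ids")
    labels = cond.reindex(knn.unit_ids).to_numpy()
    is_a = labels == cond_a
    is_b = labels == cond_b
    A, B = int(is_a.sum()), int(is_b.sum())
    if A == 0 or B == 0:
        raise ValueError(f"both conditions {conditions} must be present")
    n_units = knn.n_units
    if n_neighborhoods is None:
        n_neighborhoods = max(1, n_units // 10)
    if n_neighborhoods > n_units:
        raise ValueError("n_neighborhoods exceeds number of units")
    rng = np.random.default_rng(seed)
    index_units = np.sort(rng.choice(n_units, size=n_neighborhoods, replace=False))

    p = pseudocount
    rows = []
    for i in index_units:
        members = np.concatenate([[i], knn.neighbors[i]])
        if members.size < min_size:
            continue
        a = int(is_a[members].sum())
        b = int(is_b[members].sum())
        if a + b == 0:
            continue
        lfc = (np.log2((a + p) / (A - a + p)) - np.log2((b + p) / (B - b + p)))
        pval = _hypergeom_two_sided(a, a + b, A, A + B)
        rows.append({
            "index_unit": knn.unit_ids[i],
            "members": ",".join(knn.unit_ids[j] for j in members),
            "size": int(members.size), "n_a": a, "n_b": b,
            "lfc": float(lfc), "p": pval,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
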