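"""Pseudotime over cluster structure, branch assignment, and per-condition
density / branch-proportion summaries.

The backbone is a minimum spanning tree over cluster centroids in the
embedding; each unit is projected to the nearest backbone edge and its
pseudotime is the distance along the tree from the root to the projection.
This is a deliberately simple, fully specified trajectory method that
reproduces the readouts used downstream (ordering, branches, condition
densities); it is method-equivalent to, not a re-implementation of, any
particular published tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import Embedding

log = logging.getLogger("mucosa")

TRUNK = "trunk"


@dataclass
class PseudotimeResult:
    tau: np.ndarray                    # per-unit pseudotime, root = 0
    branch: np.ndarray                 # per-unit branch id ("1", "2", ..., "trunk")
    root_cluster: str
    backbone: nx.Graph                 # tree over cluster labels, edge attr "length"
    centroids: pd.DataFrame            # cluster x d
    unit_edge: list[tuple[str, str]]   # backbone edge each unit projects to
    unit_ids: list[str]


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                        lo: float = 0.0, hi: float = 1.0) -> tuple[float, float]:
    """(distance, projection parameter t) for segment ab, t clipped to [lo, hi].

    Leaf edges pass infinite bounds so units beyond a terminal centroid keep
    increasing pseudotime instead of piling up at the tip.
    """
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, lo, hi))
    d = float(np.linalg.norm(p - (a + t * ab)))
    return d, t


def fit_pseudotime(embedding: Embedding, clusters: Sequence[str],
                   root_scores: Optional[np.ndarray] = None,
                   root_cluster: Optional[str] = None) -> PseudotimeResult:
    """Fit the centroid-MST pseudotime.

    The root cluster is the one with the highest mean of ``root_scores``
    (e.g. a stem/naive signature score), unless given explicitly. Pseudotime
    is measured in embedding distance units along the tree.
    """
    clusters = np.asarray([str(c) for c in clusters])
    labels = sorted(set(clusters))
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters for a trajectory")
    X = embedding.coords
    centroids = pd.DataFrame(
        [X[clusters == c].mean(axis=0) for c in labels], index=labels)

    if root_cluster is None:
        if root_scores is None:
            raise ValueError("provide root_scores or root_cluster")
        root_scores = np.asarray(root_scores, dtype=float)
        means = {c: float(root_scores[clusters == c].mean()) for c in labels}
        root_cluster = max(sorted(means), key=lambda c: means[c])

    # MST over the complete centroid graph
    full = nx.Graph()
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = float(np.linalg.norm(centroids.loc[a] - centroids.loc[b]))
            full.add_edge(a, b, length=d)
    tree = nx.minimum_spanning_tree(full, weight="length")

    root_dist = nx.single_source_dijkstra_path_length(tree, root_cluster,
                                                      weight="length")
    edges = sorted(tree.edges())
    n = X.shape[0]
    tau = np.zeros(n)
    unit_edge: list[tuple[str, str]] = []
    degree = dict(tree.degree())
    for i in range(n):
        best = None
        for (u, v) in edges:
            a, b = centroids.loc[u].to_numpy(), centroids.loc[v].to_numpy()
            lo = -np.inf if degree[u] == 1 else 0.0
            hi = np.inf if degree[v] == 1 else 1.0
            d, t = _project_to_segment(X[i], a, b, lo, hi)
            # tie-break toward the edge whose nearer endpoint is closer to root
            key = (d, min(root_dist[u], root_dist[v]), u, v)
            if best is None or key < best[0]:
                best = (key, (u, v), t)
        (_, (u, v), t) = best
        # orient parent -> child along increasing root distance
        if root_dist[u] <= root_dist[v]:
            parent, length = u, tree.edges[u, v]["length"]
            offset = t * length
        else:
            parent, length = v, tree.edges[u, v]["length"]
            offset = (1.0 - t) * length
        tau[i] = root_dist[parent] + offset
        unit_edge.append((u, v) if root_dist[u] <= root_dist[v] else (v, u))
    tau -= tau.min()  # units extrapolated behind the root centroid anchor 0

    result = PseudotimeResult(
        tau=tau, branch=np.array(["1"] * n, dtype=object),
        root_cluster=root_cluster, backbone=tree, centroids=centroids,
        unit_edge=unit_edge, unit_ids=list(embedding.unit_ids))
    result.branch = assign_branches(result)
    return result


def assign_branches(result: PseudotimeResult) -> np.ndarray:
    """Label units by backbone branch.

    The branch point is the tree node of degree >= 3 nearest the root (in
    tree distance). Units projected on the root-to-branch-point path are
    ``trunk``; units beyond are labeled by the subtree their projected edge
    falls in (branches numbered deterministically by sorted subtree content).
    A path-shaped backbone yields a single branch "1".
    """
    tree = result.backbone
    root = result.root_cluster
    n = len(result.unit_edge)
    root_dist = nx.single_source_dijkstra_path_length(tree, root, weight="length")
    forks = [v for v in tree.nodes if tree.degree[v] >= 3]
    if not forks:
        return np.array(["1"] * n, dtype=object)
    branch_point = min(forks, key=lambda v: (root_dist[v], str(v)))
    trunk_path = nx.shortest_path(tree, root, branch_point, weight="length")
    trunk_edges = {frozenset(e) for e in zip(trunk_path, trunk_path[1:])}

    # components after removing the branch point; the one holding the root is trunk-side
    pruned = tree.copy()
    pruned.remove_node(branch_point)
    comps = [c for c in nx.connected_components(pruned) if root not in c]
    comps = sorted(comps, key=lambda c: sorted(c))
    comp_of: dict[str, str] = {}
    for k, comp in enumerate(comps, start=1):
        for node in comp:
            comp_of[node] = str(k)

    branch = np.empty(n, dtype=object)
    for i, (u, v) in enumerate(result.unit_edge):
        if frozenset((u, v)) in trunk_edges:
            branch[i] = TRUNK
        elif v in comp_of:       # edge oriented parent -> child
            branch[i] = comp_of[v]
        elif u in comp_of:
            branch[i] = comp_of[u]
        else:
            branch[i] = TRUNK    # edge fully on the root side of the fork
    return branch


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        spread = max(sd, 1e-3)
    return 0.9 * spread * n ** (-0.2)


def condition_density(result: PseudotimeResult, annotation: pd.DataFrame,
                      bandwidth: Optional[float] = None,
                      grid_size: int = 512) -> pd.DataFrame:
    """Gaussian kernel density of pseudotime per condition on a shared grid.

    Bandwidth defaults to Silverman's rule on the pooled pseudotime; each
    curve is normalized to integrate to 1 over the grid.
    """
    cond = annotation.set_index("unit_id")["condition"].reindex(result.unit_ids)
    tau = result.tau
    h = bandwidth if bandwidth is not None else _silverman_bandwidth(tau)
    grid = np.linspace(tau.min() - 4 * h, tau.max() + 4 * h, grid_size)
    out = {"tau": grid}
    for c in sorted(cond.dropna().unique()):
        x = tau[(cond == c).to_numpy()]
        if len(x) < 10:
            log.warning("condition %s has only %d units; density still produced",
                        c, len(x))
        dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2)
        dens = dens.sum(axis=1) / (len(x) * h * np.sqrt(2 * np.pi))
        area = np.trapezoid(dens, grid)
        out[c] = dens / area
    return pd.DataFrame(out)


def branch_proportions(result: PseudotimeResult, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-condition fraction of post-branch-point units in each branch.

    Trunk units are excluded from denominators; fractions sum to 1 per
    condition.
    """
    cond = annotation.set_index("unit_id")["condition"].reindex(result.unit_ids)
    df = pd.DataFrame({"condition": cond.to_numpy(), "branch": result.branch})
    df = df[df["branch"] != TRUNK]
    branches = sorted(df["branch"].unique())
    rows = []
    for c, grp in df.groupby("condition", sort=True):
        n = len(grp)
        for b in branches:
            rows.append({"condition": c, "branch": b,
                         "n_units": int((grp["branch"] == b).sum()),
                         "fraction": float((grp["branch"] == b).mean()) if n else 0.0})
    return pd.DataFrame(rows)
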