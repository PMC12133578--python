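"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from mucosa import synth
from mucosa.cli import main as cli_main
from mucosa.datamodel import Embedding


@pytest.fixture(scope="session")
def cell_bundle():
    """Default-scale cell simulation with a 3x abundance shift on T2 in ACD."""
    cfg = synth.CellSimConfig(
        n_types=3, n_genes=200, cells_per_sample=400,
        samples_per_condition={"HC": 3, "ACD": 3},
        abundance_shift={("T2", "ACD"): 3.0}, seed=11)
    counts, annotation, truth = synth.simulate_cells(cfg)
    return cfg, counts, annotation, truth


@pytest.fixture(scope="session")
def repertoire_bundle():
    """Repertoire with the 2% -> 10% TRBV1 usage shift and a shared pool."""
    cfg = synth.RepertoireSimConfig(
        n_clones=2000, samples_per_condition={"HC": 3, "ACD": 3},
        v_probs={"HC": [0.02] + [0.98 / 9] * 9,
                 "ACD": [0.10] + [0.90 / 9] * 9},
        public_pool_fraction=0.05, seed=7)
    table, truth = synth.simulate_repertoire(cfg)
    return cfg, table, truth


def spatial_config(seed: int = 3, **overrides) -> synth.SpatialSimConfig:
    defaults = dict(
        lattice="hex", n_rows=30, n_cols=30,
        region_layout=[
            {"region": "villus", "row_start": 0, "row_stop": 15},
            {"region": "crypt", "row_start": 15, "row_stop": 30},
            {"region": "aggregate", "center": (22, 15), "radius": 4.0},
        ],
        composition={"villus": [0.80, 0.05, 0.15],
                     "crypt": [0.55, 0.15, 0.30],
                     "aggregate": [0.10, 0.80, 0.10]},
        seed=seed)
    defaults.update(overrides)
    return synth.SpatialSimConfig(**defaults)


@pytest.fixture(scope="session")
def spatial_bundle():
    cfg = spatial_config()
    ds, truth = synth.simulate_spatial(cfg)
    return cfg, ds, truth


def make_y_topology(seed: int = 0, n_per_segment: int = 300, noise: float = 0.25):
    """Y-shaped embedding: trunk (0,0)->(4,0), arms to (8,±4), with a cluster
    spanning the fork so the centroid tree recovers the true topology.

    Returns (Embedding, true_tau, true_branch, cluster_labels).
    """
    rng = np.random.default_rng(seed)
    parts, tau_all, branch_all, clusters = [], [], [], []
    segments = [((0, 0), (4, 0), "trunk", 0.0),
                ((4, 0), (8, 4), "1", 4.0),
                ((4, 0), (8, -4), "2", 4.0)]
    for (a, b, br, t0) in segments:
        t = rng.uniform(0, 1, n_per_segment)
        pts = np.outer(1 - t, a) + np.outer(t, b)
        length = float(np.linalg.norm(np.array(b) - np.array(a)))
        pts = pts + rng.normal(0, noise, pts.shape)
        tau = t0 + t * length
        parts.append(pts)
        tau_all.append(tau)
        branch_all += [br] * n_per_segment
        for x in tau:
            if x < 2:
                lab = "c_t1"
            elif x < 3.4:
                lab = "c_t2"
            elif x < 4.8:
                lab = "c_fork"
            elif br == "1":
                lab = "c_a1" if x < 4 + 0.55 * length else "c_a2"
            else:
                lab = "c_b1" if x < 4 + 0.55 * length else "c_b2"
            clusters.append(lab)
    X = np.vstack(parts)
    emb = Embedding(coords=X, method="synthetic",
                    unit_ids=[f"u{i}" for i in range(len(X))])
    return emb, np.concatenate(tau_all), np.array(branch_all), clusters


def branch_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Best accuracy over the two branch-label permutations (trunk excluded)."""
    mask = truth != "trunk"
    p, t = np.asarray(pred)[mask], truth[mask]
    swapped = np.where(p == "1", "2", np.where(p == "2", "1", p))
    return max(float(np.mean(p == t)), float(np.mean(swapped == t)))


# ---------------------------------------------------------------------------
# full CLI pipeline, shared by the CLI suite and the acceptance criteria

def run_cli(*args: str) -> None:
    result = CliRunner().invoke(cli_main, [str(a) for a in args],
                                catch_exceptions=False)
    assert result.exit_code == 0, result.output


def run_full_cli_pipeline(root: Path) -> dict[str, Path]:
    """Run every CLI subcommand on the default synthetic bundle.

    Returns a mapping of output names to file paths for byte-comparison.
    """
    root.mkdir(parents=True, exist_ok=True)
    cells, rep, spat = root / "cells", root / "repertoire", root / "spatial"
    prep, out = root / "prep", root / "out"
    out.mkdir(exist_ok=True)

    run_cli("simulate", "cells", "--seed", 1, "--out", cells)
    run_cli("simulate", "repertoire", "--seed", 2, "--out", rep)
    run_cli("simulate", "spatial", "--seed", 3, "--out", spat)
    run_cli("preprocess", "--data", cells, "--seed", 0, "--out", prep)
    run_cli("da", "proportions", "--data", cells, "--preproc", prep,
            "--out", out / "da_prop")
    run_cli("da", "neighborhoods", "--data", cells, "--preproc", prep,
            "--seed", 0, "--out", out / "da_nbhd")
    run_cli("trajectory", "--data", cells, "--preproc", prep,
            "--root-signature", cells / "markers.gmt", "--seed", 0,
            "--out", out / "traj")
    clono = rep / "clonotypes.tsv"
    run_cli("repertoire", "overlap", "--clonotypes", clono,
            "--out", out / "overlap.tsv")
    run_cli("repertoire", "vusage", "--clonotypes", clono,
            "--out", out / "vusage.tsv")
    run_cli("repertoire", "expansion", "--clonotypes", clono,
            "--segment", "TRBV1", "--out", out / "expansion")
    run_cli("repertoire", "cdr3", "--clonotypes", clono, "--motif", "L[QG]",
            "--out", out / "cdr3")
    run_cli("repertoire", "sharing", "--clonotypes", clono,
            "--out", out / "sharing.tsv")
    run_cli("spatial", "regions", "--data", spat, "--seed", 0,
            "--out", out / "regions.tsv")
    regions = out / "regions.tsv"
    run_cli("spatial", "adjacency", "--data", spat, "--regions", regions,
            "--out", out / "adjacency")
    run_cli("spatial", "deconvolve", "--data", spat,
            "--signatures", spat / "signatures.tsv", "--regions", regions,
            "--out", out / "deconv")
    run_cli("spatial", "coloc", "--weights", out / "deconv" / "weights.tsv",
            "--out", out / "coloc")
    biggest = (pd.read_csv(regions, sep="\t")["region"]
               .value_counts().idxmax())
    run_cli("spatial", "markers", "--data", spat, "--regions", regions,
            "--region", biggest, "--out", out / "markers.tsv")
    gmt = root / "sets.gmt"
    gmt.write_text("immune\tna\t" +
                   "\t".join(f"G{i:04d}" for i in range(10, 20)) + "\n")
    run_cli("spatial", "enrich", "--data", spat, "--regions", regions,
            "--gmt", gmt, "--n-perm", 99, "--seed", 0,
            "--out", out / "enrich.tsv")
    pairs = root / "pairs.tsv"
    pairs.write_text("ligand\treceptor\tpair_name\nG0000\tG0010\tp1\n"
                     "G0011\tG0015\tp2\n")
    run_cli("ligrec", "celltypes", "--data", cells, "--preproc", prep,
            "--pairs", pairs, "--n-perm", 99, "--seed", 0,
            "--out", out / "ligrec_celltypes.tsv")
    run_cli("ligrec", "regions", "--data", spat, "--regions", regions,
            "--pairs", pairs, "--out", out / "ligrec_regions.tsv")

    outputs = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            outputs[str(p.relative_to(root))] = p
    return outputs


@pytest.fixture(scope="session")
def cli_pipeline_runs(tmp_path_factory):
    """Two identical full pipeline runs plus their wall-clock times."""
    base = tmp_path_factory.mktemp("cli")
    t0 = time.time()
    run1 = run_full_cli_pipeline(base / "run1")
    t1 = time.time()
    run2 = run_full_cli_pipeline(base / "run2")
    return {"run1": run1, "run2": run2,
            "elapsed_first": t1 - t0, "elapsed_total": time.time() - t0}
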