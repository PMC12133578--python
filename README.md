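# mucosa

Statistics toolkit for multi-condition (healthy control / active disease /
treated disease) studies of the intestinal mucosa combining single-cell
transcriptomics, TCR repertoire sequencing, and spot-based spatial
transcriptomics. It bundles, as a tested and reusable pipeline:

- **Composition & neighborhood differential abundance** — per-sample cluster
  proportion tests (exact Mann–Whitney) and KNN-neighborhood enrichment with
  per-neighborhood log fold change, hypergeometric p-values and BH FDR.
- **Pseudotime branching by condition** — centroid-MST pseudotime, branch
  assignment at the first fork, per-condition density along pseudotime and
  branch proportions.
- **TCR repertoire skewing** — Morisita–Horn overlap, per-segment
  negative-binomial V-usage tests with BH, unique / top-expanded V-segment
  fractions, expansion-quintile Fisher enrichment, CDR3 amino-acid
  composition, motif frequencies and inter-sample sequence sharing.
- **Spatial niche analysis** — lattice-aware region clustering, region
  adjacency networks (row-stochastic ordered neighbor-pair fractions), NNLS
  signature deconvolution, cell-type colocalization, region markers and
  expression-matched permutation gene-set enrichment.
- **Receptor–ligand & susceptibility-gene scoring** — label-permutation
  scored ligand–receptor interactions between cell types, per-region pair
  coexpression scores, and gene-set scores per cell type.
- **Synthetic data generators** — negative-binomial cell populations with
  marker blocks and condition-dependent abundance shifts, clonotype tables
  with biased V usage and power-law clonal expansion, and hex/square spot
  lattices with banded plus focal circular regions — all with recorded ground
  truth, so every statistical claim is testable.

All I/O is plain text: Matrix Market + name files (or dense TSV), annotation
TSV, AIRR-C rearrangement TSV, GMT gene sets, receptor–ligand TSV, spot
coordinate TSV; outputs are TSV/JSON, networks as edge-list TSV.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle equivalence,
test calibration/power at fixed seeds, exact enumerated examples, recovery on
synthetic ground truth, CLI determinism and an end-to-end smoke run). All
fixtures are generated programmatically; the full suite runs in a few minutes
on one CPU.

## CLI

Every command logs its resolved config and seed, and is deterministic:
rerunning with the same inputs produces byte-identical outputs.

```bash
# synthetic data with ground truth
mucosa simulate cells      --seed 1 --out data/cells
mucosa simulate repertoire --seed 2 --out data/repertoire
mucosa simulate spatial    --seed 3 --out data/spatial

# shared preprocessing: normalize -> HVG -> PCA -> KNN -> Leiden
mucosa preprocess --data data/cells --seed 0 --out prep

# differential abundance
mucosa da proportions   --data data/cells --preproc prep --out out/da_prop
mucosa da neighborhoods --data data/cells --preproc prep --seed 0 --out out/da_nbhd

# pseudotime + branches
mucosa trajectory --data data/cells --preproc prep \
    --root-signature data/cells/markers.gmt --out out/traj

# repertoire statistics (AIRR rearrangement TSV)
mucosa repertoire overlap   --clonotypes data/repertoire/clonotypes.tsv --out out/overlap.tsv
mucosa repertoire vusage    --clonotypes data/repertoire/clonotypes.tsv --out out/vusage.tsv
mucosa repertoire expansion --clonotypes data/repertoire/clonotypes.tsv --segment TRBV1 --out out/expansion
mucosa repertoire cdr3      --clonotypes data/repertoire/clonotypes.tsv --out out/cdr3
mucosa repertoire sharing   --clonotypes data/repertoire/clonotypes.tsv --out out/sharing.tsv

# spatial niches
mucosa spatial regions    --data data/spatial --seed 0 --out out/regions.tsv
mucosa spatial adjacency  --data data/spatial --regions out/regions.tsv --out out/adj
mucosa spatial deconvolve --data data/spatial --signatures data/spatial/signatures.tsv \
    --regions out/regions.tsv --out out/deconv
mucosa spatial coloc      --weights out/deconv/weights.tsv --out out/coloc
mucosa spatial markers    --data data/spatial --regions out/regions.tsv --region R0 --out out/markers.tsv
mucosa spatial enrich     --data data/spatial --regions out/regions.tsv --gmt sets.gmt --out out/enrich.tsv

# receptor-ligand scoring
mucosa ligrec celltypes --data data/cells --preproc prep --pairs pairs.tsv --out out/lr_ct.tsv
mucosa ligrec regions   --data data/spatial --regions out/regions.tsv --pairs pairs.tsv --out out/lr_rg.tsv
```

`simulate` subcommands accept `--config cfg.yaml` with keys mirroring the
`CellSimConfig` / `RepertoireSimConfig` / `SpatialSimConfig` dataclasses in
`mucosa.synth`.

## Package layout

| module | contents |
| --- | --- |
| `mucosa.datamodel` | validated containers (counts, annotations, clonotypes, lattices, gene sets) |
| `mucosa.io` | readers/writers for all on-disk formats, config + run logging |
| `mucosa.synth` | synthetic data generators with ground truth |
| `mucosa.preprocess` | normalization, HVG, PCA, KNN, Leiden, signature scoring |
| `mucosa.diff_abundance` | proportion tests, neighborhood enrichment |
| `mucosa.trajectory` | centroid-MST pseudotime, branches, densities |
| `mucosa.repertoire` | overlap, V usage, expansion, CDR3, sharing |
| `mucosa.spatial` | neighbors, regions, adjacency, deconvolution, colocalization, enrichment |
| `mucosa.ligrec` | receptor–ligand and gene-set scoring |
| `mucosa.cli` | `mucosa` command-line interface |
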