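# morphnet

Single-subject gray-matter **morphological similarity networks**: build a
symmetric ROI × ROI similarity matrix from a registered gray-matter density
volume by tiling it into 3×3×3-voxel cubes and taking, for every cube pair,
the maximum Pearson correlation over the 24 proper cube rotations; then
threshold, compute graph-theory measures, and run covariate-adjusted group
inference — including permutation-based edge statistics — across a cohort.

A first-class synthetic-data module generates registered volumes, toy
atlases and cohort tables (39-item life-event ratings plus covariates) with
controllable inter-regional similarity, planted edge effects and planted
hubs, so the entire pipeline runs and is tested without any data download.

## What's inside

| module | role |
| --- | --- |
| `morphnet.synthetic` | synthetic volumes, atlases, cohorts with planted effects |
| `morphnet.stress` | life-event questionnaire scoring, Low/High stress-group cut-offs |
| `morphnet.cubes` | cube tiling, 24-rotation similarity, ROI matrix resizing |
| `morphnet.construction` | Fisher r-to-z, proportional sparsity thresholding, binarization |
| `morphnet.metrics` | degree, clustering, betweenness, path length, efficiency, small-worldness (from scratch; networkx used only as a test oracle) |
| `morphnet.inference` | 2-SD hub detection, linear-model group tests, BH-FDR, partial correlation |
| `morphnet.nbs` | permutation edge statistics (`edge_fdr`, `edge_fwer`, `component` modes) |
| `morphnet.io` / `morphnet.pipeline` / `morphnet.cli` | NIfTI/TSV/CSV formats, manifests, end-to-end runner |

## Command line

```bash
# generate a demo cohort (volumes + atlas + cohort CSV + config)
morphnet gen-data --out demo --n-low 12 --n-high 12 --n-roi 16 --grid 27 --seed 1

# run everything: score -> extract -> threshold -> metrics -> compare ->
# correlate -> nbs; outputs land in demo/results with JSON manifests
morphnet -v run-all demo/config.yaml
```

Each stage is also available as its own subcommand (`score`, `extract`,
`threshold`, `metrics`, `compare`, `correlate`, `nbs`) operating on the same
config file. Reruns with the same config and seed are bit-identical.

Key outputs: per-subject ROI matrices (`matrices/*_{r,z}.tsv`), per-sparsity
edge lists (`networks/`), `global_metrics.csv`, `nodal_metrics.csv`,
`group_stats.csv` (with BH-corrected p-values per metric × sparsity family),
`hubs.csv`, `partial_correlations.csv`, and `nbs_edges.tsv`.

## Conventions worth knowing

- Cube similarity maximizes over the 24 orientation-preserving rotations
  only (no reflections); constant cubes correlate 0 by convention.
- Proportional thresholding keeps `round(s · n(n−1)/2)` edges, ties broken
  by value then (row, column), which makes edge sets nested across levels.
- Path length averages over *reachable* ordered pairs and the unreachable
  fraction is reported; betweenness is unnormalized, unordered-pair.
- Small-worldness normalizes by degree-preserving edge-swap null networks
  (20 by default, seeded).
- Stress groups: Low = at most 5 negative events with total in [−5, 0];
  High = 6+ events with total in [−20, −11]; everything else is
  Unclassified and excluded from group analyses.
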