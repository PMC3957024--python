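# raftlink

Analysis pipeline for detergent-based membrane fractionation studies: from
label-free peptide evidence and lipid peak intensities to

1. proteins with significantly altered **DRM/DSF partitioning** between a
   wildtype and a mutant genotype (bootstrap ratio-shift score with a
   genotype-label-permutation FDR threshold),
2. **differentially abundant lipids** (low-variation reference-set
   normalization, z/log2 transformation, Welch t-tests at species and class
   level), and
3. a significance-filtered **lipid–protein correlation network** (edge score
   = lipid log2 fold change x protein ratio-shift score, thresholded against
   a randomized-pairing null), with degrees, annotations, and two-mutant
   subnetwork extraction.

A first-class synthetic-data module generates peptide evidence tables
(MaxQuant `evidence.txt` dialect), sample designs, lipid tables, peak/marker
tables and annotation tables with planted ground truth (partitioning shifts,
co-purifying proteins, lipid fold changes, protein–lipid coupling), enabling
calibration and recovery testing of every stage.

## Layout

| module | role |
|---|---|
| `raftlink.synthetic` | generators with planted ground truth |
| `raftlink.quant` | peptide filtering (70% fraction-presence rule), total-ion normalization, median-scale/median-average protein aggregation |
| `raftlink.ratio_shift` | bootstrap DRM/DSF ratio-shift score, permutation FDR calibration |
| `raftlink.copurify` | SP/IM co-purification flagging (highest-mean rule + one-sided Welch tests) and result filtering |
| `raftlink.lipidomics` | mode merging, normalization, transformation, differential tests, RT correction, library matching |
| `raftlink.network` | edge scoring, permutation edge FDR, bipartite graph construction, subnetworks |
| `raftlink.pipeline` / `raftlink.cli` | orchestration, manifests, CLI |

## CLI

```bash
raftlink simulate --seed 1 --n-proteins 200 --outdir simulated
raftlink quant simulated/evidence.tsv simulated/design.tsv --out matrix.tsv
raftlink ratio-shift matrix.tsv simulated/design.tsv --fdr 0.01 --seed 1
raftlink copurify matrix.tsv simulated/design.tsv --alpha 0.01
raftlink lipid-normalize simulated/lipids_pos.tsv simulated/lipids_neg.tsv
raftlink lipid-diff lipids_normalized.tsv lipid_design.tsv
raftlink lipid-annotate peaks.tsv library.tsv --markers markers.tsv --ppm-tol 5 --rt-tol 0.5
raftlink network ratio_shift_results.tsv lipid_results.tsv --fdr 0.01
raftlink run-all --config run.yaml --seed 1 --outdir out
```

`run-all` executes simulate → quantify → ratio-shift → co-purification filter
→ lipidomics → network, writing every intermediate table, a `manifest.json`
(parameters, seed, checksums; byte-identical across reruns with the same
config and seed) and a `summary.txt`. Configuration is a YAML file mirroring
`SimulationConfig` and `AnalysisParams`; defaults are the study settings
(70% presence, FDR 1%, alpha 0.01/0.05, 5 ppm, 0.5 min).

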