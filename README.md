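# g4meth

Joint analysis of G-quadruplex (G4) signal, DNA 5mC methylation and
chromatin accessibility around transcription start sites — with a coupled
synthetic multi-omics generator for end-to-end validation.

## The problem

Only a minority of putative quadruplex-forming sequences (PQSs) fold into
G4 structures in cells, and promoter G4s are strongly associated with
active transcription. One proposed regulator is CpG methylation: if 5mC
inhibits G4 folding, then hypomethylated promoters should show more G4
signal than hypermethylated ones *at equal PQS content*, in both open and
closed chromatin, and genome-wide demethylation (e.g. a DNMT1 knockout)
should raise G4 signal and the expression of G4-promoter genes. Testing
this requires integrating four assays: bisulfite sequencing (per-CpG
methylation counts), G4 CUT&Tag with an IgG control, ATAC-seq, and RNA-seq
differential expression.

`g4meth` provides the full analysis path for researchers working with such
data:

- **`core_tracks`** — BED/bedGraph I/O, sparse signal tracks, BPM
  (bins-per-million) depth normalization, floored IgG background
  subtraction, interval overlap, and a threshold peak caller for synthetic
  tracks.
- **`pqs_scan`** — canonical PQS detection, pattern
  G₃₊N₁₋₁₂G₃₊N₁₋₁₂G₃₊N₁₋₁₂G₃₊, both strands, greedy leftmost-longest
  selection, with CpG annotation. Verified against an exhaustive
  brute-force oracle.
- **`methylome`** — site level = 100·mC/total, unweighted window levels,
  and ranked hyper/hypomethylated transcript selection (TSS ± 1 kb,
  top-N each way, one transcript per gene).
- **`meta_signal`** — TSS-anchored 10-bp-bin matrices (strand-oriented),
  mean profiles ± SEM, methylation-sorted heatmap ordering, PQS density
  matrices, and hypo/hyper profile ratios.
- **`integrate`** — the joint PQS table (G4 peak, G4/ATAC signal,
  open/closed, methylation state), Pearson G4–ATAC coupling, the
  accessibility × methylation stratified comparison (Student's t),
  MAnorm-style non-differential ATAC peak selection, per-chromosome
  KO/WT log2 ratios, the strict DE filter (p < 0.05, |log2FC| > 1) and
  promoter-G4 linkage for upregulated genes.
- **`synthetic_data`** — a generator with known ground truth implementing
  the causal model P(G4 forms) = σ(β0 + β_m(1−m) + β_a·a): methylation m
  inhibits formation, accessibility a promotes it, and promoter G4
  occupancy scales expression. Includes in-silico bisulfite conversion
  and coupling calibration by bisection.
- **`pipeline` / `g4m` CLI** — one declarative config drives
  simulate → scan → select → profile → integrate with a deterministic
  JSON report.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

Run the packaged default configuration (240 genes on 3 chromosomes, two
planted PQSs per promoter, a wild type and a half-methylation knockout):

```bash
g4m run --config src/g4meth/data/default_config.yaml --out scratch/demo --seed 1
```

The report (`scratch/demo/report.json`) from this exact command contains,
among other sections:

```json
 "methylation": { "n_hyper": 60, "n_hypo": 60 },
 "pqs": { "n_total": 538, "n_plus": 267, "n_minus": 271 },
 "pearson_g4_atac": 0.1654,
 "chrom_log2_ratio": { "chr1": 0.165, "chr2": 0.131, "chr3": 0.231 },
 "de": { "n_up": 25, "n_down": 0 },
 "promoter_g4_link": { "mean_delta": 2.344, "n_resolved": 25, "paired_p": 3.6e-09 }
```

Reading: 538 PQSs were detected (480 planted plus chance background
matches, both strands); transcripts split into 60 hyper- and 60
hypomethylated promoters; per-PQS G4 signal correlates weakly positively
with ATAC signal (r = 0.165 at the default coupling β_a = 1); the knockout
raises background-subtracted G4 signal on every chromosome
(log2 ratios 0.13–0.23); differential expression is strongly asymmetric
(25 up vs 0 down), and those upregulated genes gain promoter G4 signal
(mean Δ = +2.34 BPM units, paired p ≈ 4e-09) — the full causal chain
demethylation → G4 gain → transcription is visible end to end. (Numbers
above are for `--seed 1`; any rerun with the same config and seed
reproduces them exactly.)

The stratified comparison lives in `strata_summary.tsv` and the per-PQS
annotations in `pqs_joint_table.tsv`.

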