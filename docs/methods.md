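# Methods

`g4meth` implements a genome-wide joint analysis of three epigenomic layers —
DNA 5mC methylation, G-quadruplex (G4) signal, and chromatin accessibility —
around transcription start sites, plus the linkage of promoter G4 changes to
differential expression, and a coupled synthetic multi-omics generator that
embodies one causal hypothesis: *methylation inhibits G4 formation,
accessibility weakly promotes it, and promoter G4s elevate transcription*.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data can and cannot show.

## Coordinate and track model

All coordinates are 0-based half-open (BED/bedGraph native); readers of
1-based formats must convert at the boundary. A signal track is a set of
sorted, disjoint runs of constant non-negative value per chromosome;
uncovered bases read as 0. Overlap between intervals means at least one
shared base; half-open adjacency does not overlap. Depth normalization is
bins-per-million (BPM): every value is scaled by 1e6 / total mapped reads.
Background correction subtracts an IgG track per base and floors at zero;
this floored difference is positively biased wherever signal and background
are both near zero (see "Knockout chromosome ratios" below for where this
matters).

## Canonical PQS detection

A canonical putative quadruplex-forming sequence (PQS) is
G₃₊ N₁₋₁₂ G₃₊ N₁₋₁₂ G₃₊ N₁₋₁₂ G₃₊: four tracts of at least `run_min_len = 3`
consecutive guanines separated by three loops of `loop_min_len = 1` to
`loop_max_len = 12` arbitrary bases (N allowed in loops, never in tracts).
Bulged or mismatched tracts and scoring models are out of scope; at this
parameterization detection reduces to the pattern itself.

Selection within a strand is greedy: among all substrings matching the
pattern, the leftmost-starting (then longest) match is kept, overlapping
candidates are discarded, and scanning resumes past its end. The greedy
rule is deliberate — published tools do not document their tie-breaking at
this parameterization — and an exhaustive regex oracle (all substrings,
same greedy selection) defines ground truth in the test suite. The scanner
itself chains maximal G-runs with a memoized longest-completion search,
which the tests show equivalent to the oracle on thousands of random
sequences. Minus-strand PQSs come from scanning the reverse complement and
mapping coordinates back, making strand symmetry exact by construction;
plus- and minus-strand PQSs may overlap. A CpG is counted once per
dinucleotide, by the plus-strand position of its C, and only when both
bases lie inside the PQS interval.

## Methylation levels and transcript selection

The site methylation level is 100 · mC / total over the reads covering a
cytosine; a site with zero coverage has no level (it is excluded, not 0%).
A window level is the **unweighted** mean of site levels over covered CpGs
in the window — deep and shallow sites count equally, matching the
convention of averaging per-cytosine ratios. Windows need `min_sites = 1`
covered CpG by default, otherwise the level is undefined.

Transcripts are ranked by the level over TSS ± 1 kb; the `top_n` highest
form the hypermethylated list, the `top_n` lowest the hypomethylated list,
and within each list only the most extreme-ranked transcript per gene is
kept (ties broken by lexicographic transcript id, which makes the selection
fully deterministic). With fewer than `2·top_n` rankable transcripts both
lists shrink to half the rankable count so they remain disjoint.

A PQS's methylation state is the mean site level over its covered CpGs:
"high" strictly above 50%, "low" at or below (a mean of exactly 50% is
low), "undefined" with no covered CpG. The phrase "containing CpG sites
with a methylation rate greater than 50%" is ambiguous between a mean-level
and an any-site reading; the mean is the default and `mode="any"` exposes
the alternative. CpG dyad strands are never merged; calls are consumed at
the granularity they are provided.

## TSS metaprofiles

Anchored matrices hold one row per transcript and one column per 10-bp bin
across TSS ± 1 kb (200 columns). Cells are base-weighted mean signal per
bin; rows of minus-strand transcripts are reversed so column 0 is always
1 kb upstream in reading direction. Windows that would extend past a
contig edge are dropped with a warning, not zero-padded. PQS density
matrices count PQS bases per bin divided by bin width, pooling both strands
(overlaps add). Heatmap rows are ordered by decreasing row-mean of a key
matrix (methylation), stably for ties.

The hypo/hyper profile ratio is per-bin (hypo + ε)/(hyper + ε) with
pseudocount ε = 1e-3 on profile units (how zero bins were handled upstream
is not documented anywhere, so the pseudocount is explicit and small).
Because extremes over the full 2-kb window and over the TSS-proximal
sub-window can differ, the ratio reports min/max over all bins *and* over
± 200 bp around the TSS, plus the proximal mean.

## Joint PQS table and stratification

Each PQS carries: mean G4 signal and mean ATAC signal over its interval,
whether it overlaps a G4 peak, whether it overlaps an ATAC peak ("open"),
and its methylation state. "Signal at the PQS" means the mean over the PQS
interval, not a window around each CpG (a `--cpg-window` style alternative
is available via `pqs_methylation_state` options). The analysis set filter
keeps PQSs under a G4 peak containing at least one CpG. The G4-ATAC
coupling is the sample Pearson correlation on raw (BPM-scale) signals —
Pearson is invariant to the BPM scale factor; a log2(1+x) option exists.
The 3 × 3 summary (all / open / closed × all / hypo / hyper) uses
equal-variance Student's t for pairwise comparisons (Welch by flag);
undefined-methylation PQSs contribute to accessibility strata only, so
open = open×hypo + open×hyper + open×undefined holds exactly.

Non-differential ATAC peak selection is a deliberate simplification of
MAnorm: M = log2((a+1)/(b+1)) per common peak, rescaled by subtracting the
median M over common peaks (absorbing global depth shifts), retaining
|M| ≤ 1. The robust-regression component of MAnorm is not reproduced.

The DE filter is strict: up means p < 0.05 and log2FC > 1; down means
p < 0.05 and log2FC < −1; a gene at exactly |log2FC| = 1 is excluded.
Promoter-G4 linkage averages each gene's matrix row (TSS ± 1 kb) per
condition and tests the per-gene KO − WT differences with a paired t.

## The synthetic generator

The generator is first-class, tested code; its defaults define the
simulated study conditions and every output is a pure function of
(config, seed). Structural randomness (genome, promoter states,
accessibility, true methylation levels) is shared between conditions;
only counting noise differs, so a knockout is a pure intervention.

**Genome.** One gene per 4 kb, TSSs evenly spaced, strands alternating.
Each promoter (TSS ± 900 bp) receives `n_pqs_per_promoter` canonical
motifs on the gene strand (tracts of 3–4 G, loops 1–7 bases, a CG planted
in the middle loop so every PQS contains a CpG), each wrapped in a 14-bp
A/T buffer. The buffer guarantees the scanner recovers planted coordinates
exactly — no G-run can chain across it — which the tests use as ground
truth. The random background still produces occasional chance PQSs
(roughly one per 20 kb per strand pair at uniform base composition), which
is realistic and exercises the no-G4-peak filter path.

**Methylome.** Each promoter is hypermethylated (mean true level 0.85) or
hypomethylated (0.10) with probability `promoter_hyper_fraction = 0.5`;
per-CpG true levels are Beta-distributed around the state mean
(concentration 20), read depth is Poisson(30), methylated counts Binomial.
The knockout multiplies every true level by `ko_meth_scale = 0.5` while
keeping states and Beta draws, mimicking a genome-wide demethylation.
Calls are emitted for CpGs within 1.1 kb of a TSS (the analysis windows);
distal chance PQSs therefore have undefined methylation, as intended.

**Accessibility.** A fraction `open_fraction = 0.5` of promoters is open;
accessibility a ~ Beta(6,2) for open and Beta(2,6) for closed promoters.
Every promoter's ATAC plateau rate is `atac_amplitude · a` over TSS ± 1 kb
on top of Poisson background (0.2/bin) — the bulk ATAC signal tracks
accessibility continuously — while only open-promoter windows are called
peaks. The plateau spans the whole promoter so that every planted PQS's
measured ATAC signal reflects its promoter's accessibility.

**G4 signal.** Per PQS the formation probability is

    P(form) = 1 / (1 + exp(−(β0 + β_m·(1 − m) + β_a·a)))

with m the mean true methylation of the PQS's CpGs and defaults β0 = −2,
β_m = 3, β_a = 1. The coverage bump height is `g4_amplitude · P(form)`
times log-normal noise (σ = 0.25): a bulk experiment averages over cells,
so occupancy — not a single Bernoulli event — drives coverage. The
Bernoulli formation indicator is still drawn and stored for recovery
tests. Note the inhibition acts through (1 − m): raising β_m raises
formation for every m < 1 but much faster for hypomethylated PQSs, so the
observable consequence of stronger inhibition is a wider hypo − hyper
formation gap (this is the monotonicity the tests assert). The G4 library
is background-dominated (Poisson 10/bin against bump amplitude 100, i.e.
the specific signal is a minority of reads, as when sequencing depth is
fixed regardless of G4 abundance); this matters because BPM normalization
fixes the genome-wide track total, and only the *concentration* of signal
into peaks — revealed after IgG subtraction — can show a global G4 gain.
The floored per-base subtraction of two Poisson backgrounds leaves a
positive residual ~ sqrt(λ) per bin; with λ = 10 and amplitude 100 the
bump signal dominates that residual and the knockout raises the
per-chromosome background-subtracted totals by ≈ 0.1–0.25 log2 units.
Peaks are bump footprints (PQS ± 50 bp) whose noiseless height reaches
`g4_peak_min = 10`, merged.

**Expression.** Gene expression mean is base · (1 + effect · occupancy)
with occupancy the mean formation probability over the gene's promoter
PQSs, base log-normal around 200, effect 8, negative-binomial counts with
dispersion 0.1 and 3 replicates per condition. The DE table is computed
naively — empirical log2 fold change with +0.5 pseudocount and a per-gene
Student's t on log2(count+1) — deliberately not a shrinkage DE method.
The expected log2FC implied by the latent occupancies is stored for power
checks.

**Coupling calibration.** `calibrate_coupling` bisects β_a until the mean
(over ≥ 5 seeds) Pearson correlation of the filtered joint table matches a
target within tolerance. Genome, methylome and accessibility realizations
are cached per seed and only the G4 layer is re-simulated per candidate
(common random numbers), making the response curve smooth and monotone over
the default bracket β_a ∈ [0, 4], where it spans roughly −0.03 to 0.39
under default noise. A target outside the bracketed range raises an error
reporting both bracket values. The packaged fixture configuration
calibrates on 2,000-promoter cohorts to tolerance 0.01 and validates on an
independent 10,000-promoter (≈ 20,000 PQS) cohort.

**Bisulfite conversion** is modeled at 100% efficiency: every unmethylated
C reads as T, methylated Cs are protected. A conversion-failure rate is
not simulated by default.

## What the simulation does and does not show

The generator reproduces the qualitative structure of the real analyses:
methylation-stratified G4 profiles, accessibility × methylation strata,
knockout chromosome-wide gains, and the up-DEG promoter-G4 linkage. It
does **not** emulate read-level artifacts (mappability, duplicates, GC
bias), CpG islands or realistic CpG spacing, replicate batch effects,
fragment-size structure, distal regulatory elements, or transcript
isoform complexity (one transcript per gene; per-gene deduplication is
exercised by unit fixtures instead). Passing tests therefore demonstrate
the correctness and sensitivity of the *analysis machinery* under the
stated causal model, not the biological claims themselves.

## Problem sizes and numerics

Simulated cohorts use 600–2,000 genes (4 chromosomes) for pattern checks
and 2,000/10,000 genes for correlation calibration/validation — sizes
chosen so each check completes in minutes on a single core while leaving
every assertion's margin far above its noise floor. Ties in ranking and
row ordering are resolved stably and deterministically; degenerate inputs
(zero-coverage sites, empty strata, zero-variance correlations, windows at
contig edges) return the documented undefined/None/error outcomes rather
than silent zeros. Seeds derive from a single integer via fixed per-stage
entropy tuples, so every artifact is reproducible from (config, seed).
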