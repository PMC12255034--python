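"""Coupled synthetic multi-omics generator with known ground truth.

The generator emits a toy genome with canonical PQS motifs planted in
promoter windows, a promoter-stratified CpG methylome, an accessibility
track with open/closed promoters, a G4 signal track whose per-PQS formation
follows a logistic causal model, and a replicate expression table coupled to
promoter G4 occupancy:

    P(G4 forms) = sigmoid(beta0 + beta_m * (1 - m) + beta_a * a)

with m the mean true methylation of the PQS's CpGs (0..1) and a the
promoter accessibility (0..1).  Methylation *inhibits* formation
(beta_m > 0 acts on 1 - m), accessibility weakly promotes it, and formed
promoter G4s elevate transcription: expression mean scales by
(1 + effect * occupancy).  The G4 coverage bump height is proportional to
the formation probability (a bulk signal averages over cells), while the
Bernoulli formation indicator is kept in the truth tables for recovery
tests.  A DNMT1-knockout-like condition rescales every true methylation
level by ``ko_meth_scale`` while sharing the genome, promoter states and
accessibility with the wild type.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_tracks import GenomeInterval, PeakSet, SignalTrack
from .methylome import MethylCalls, TranscriptAnchor
from .pqs_scan import revcomp

_STAGE_GENOME, _STAGE_METH, _STAGE_ATAC, _STAGE_G4, _STAGE_EXPR = 1, 2, 3, 4, 5
_COND_IDX = {"WT": 0, "KO": 1}


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs; defaults define the simulated study conditions."""

    n_genes: int = 1000
    n_chroms: int = 4
    n_pqs_per_promoter: int = 2
    gene_spacing: int = 4000  # bp between TSSs; genome_length = n_genes * spacing
    promoter_hyper_fraction: float = 0.5
    hyper_level: float = 0.85  # mean true methylation of hypermethylated promoters
    hypo_level: float = 0.10
    level_concentration: float = 20.0  # Beta concentration around the state mean
    meth_window: int = 1100  # half-width of the CpG-call window around each TSS
    coverage_mean: float = 30.0  # Poisson read depth per CpG
    open_fraction: float = 0.5
    atac_amplitude: float = 8.0  # plateau rate scale at fully accessible promoters
    atac_background: float = 0.2  # Poisson rate per bin outside peaks
    atac_halfwidth: int = 1000
    beta0: float = -2.0
    beta_m: float = 3.0  # methylation inhibition of G4 formation
    beta_a: float = 1.0  # accessibility promotion of G4 formation
    g4_amplitude: float = 100.0  # bump rate scale for a fully formed G4
    g4_amp_sigma: float = 0.25  # log-normal amplitude noise (sigma of log)
    g4_background: float = 10.0  # Poisson rate per bin (also the IgG rate); the library is background-dominated, as in a fixed-depth experiment
    g4_peak_min: float = 10.0  # min noiseless bump height to count as a peak
    g4_bump_pad: int = 50  # bump extends this far beyond the PQS
    bin_size: int = 10
    expr_base_mean: float = 200.0
    expr_base_sigma: float = 0.5
    expr_effect: float = 8.0  # expression mean scales by (1 + effect * occupancy)
    expr_dispersion: float = 0.1
    n_replicates: int = 3
    condition: str = "WT"
    ko_meth_scale: float = 0.5

    def __post_init__(self) -> None:
        for name in ("promoter_hyper_fraction", "open_fraction", "hyper_level", "hypo_level"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if not 0 < self.ko_meth_scale <= 1:
            raise ValueError("ko_meth_scale must be in (0, 1]")
        if self.condition not in _COND_IDX:
            raise ValueError("condition must be WT or KO")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_spacing < 4000:
            raise ValueError("gene_spacing must be >= 4000 (promoters must fit)")

    @property
    def genome_length(self) -> int:
        return self.n_genes * self.gene_spacing

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown SimConfig keys: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SimTruth:
    """Latent generator state: per-gene and per-PQS ground truth."""

    genes: pd.DataFrame  # gene_id, transcript_id, chrom, tss, strand, [hyper, accessibility, open, ...]
    pqs: pd.DataFrame  # chrom, start, end, strand, gene_idx, [true_meth, p_form, formed, amplitude, ...]
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)
    cpg_true_level: dict[str, np.ndarray] = field(default_factory=dict)


def _rng(seed: int, stage: int, condition: str | None = None):
    entropy = [int(seed), stage]
    if condition is not None:
        entropy.append(_COND_IDX[condition])
    return np.random.default_rng(entropy)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)
_AT = np.frombuffer(b"AT", dtype=np.uint8)
_LOOP_LETTERS = np.frombuffer(b"ACT", dtype=np.uint8)  # loops kept G-free


def _random_motif(rng) -> bytes:
    """One canonical PQS motif with >= 1 CpG planted in the middle loop.

    Tracts of 3-4 G; loops 1-7 bases from {A,C,T} except the middle loop,
    which starts with CG (the planted CpG) followed by 1-5 G-free bases so
    the lone loop G can never seed a tract.
    """
    parts = []
    for k in range(4):
        t = int(rng.integers(3, 5))
        parts.append(b"G" * t)
        if k == 3:
            break
        if k == 1:
            tail = rng.integers(0, 3, size=int(rng.integers(1, 6)))
            parts.append(b"CG" + _LOOP_LETTERS[tail].tobytes())
        else:
            loop = rng.integers(0, 3, size=int(rng.integers(1, 8)))
            parts.append(_LOOP_LETTERS[loop].tobytes())
    return b"".join(parts)


_PLANT_BUFFER = 14  # G/C-free bases flanking each planted motif


def generate_genome(
    config: SimConfig, seed: int
) -> tuple[dict[str, str], list[TranscriptAnchor], SimTruth]:
    """Random background genome with PQS motifs planted in promoters.

    TSSs are evenly spaced (one gene per ``gene_spacing`` bp) with
    alternating strands; each promoter (TSS +- 900 bp) receives
    ``n_pqs_per_promoter`` motifs on the gene strand, each wrapped in a
    14-bp A/T buffer so the planted coordinates are recovered exactly by
    the scanner.  Deterministic given (config, seed).
    """
    rng = _rng(seed, _STAGE_GENOME)
    per_chrom = config.n_genes // config.n_chroms
    counts = [per_chrom] * config.n_chroms
    for i in range(config.n_genes - per_chrom * config.n_chroms):
        counts[i] += 1
    if min(counts) < 1:
        raise ValueError("more chromosomes than genes")
    npqs = config.n_pqs_per_promoter
    slot = 1800 // max(npqs, 1)
    if npqs and slot < 40 + 2 * _PLANT_BUFFER:
        raise ValueError("n_pqs_per_promoter too large for a 1.8 kb promoter")

    genome: dict[str, str] = {}
    anchors: list[TranscriptAnchor] = []
    gene_rows, pqs_rows = [], []
    gene_idx = 0
    for ci, n_here in enumerate(counts):
        chrom = f"chr{ci + 1}"
        length = n_here * config.gene_spacing
        seq = _LETTERS[rng.integers(0, 4, length)].copy()
        for gi in range(n_here):
            tss = gi * config.gene_spacing + config.gene_spacing // 2
            strand = "+" if gene_idx % 2 == 0 else "-"
            gene_id = f"g{gene_idx:05d}"
            anchors.append(TranscriptAnchor(gene_id, f"{gene_id}.t1", chrom, tss, strand))
            gene_rows.append(
                {"gene_id": gene_id, "transcript_id": f"{gene_id}.t1", "chrom": chrom,
                 "tss": tss, "strand": strand}
            )
            for k in range(npqs):
                motif = _random_motif(rng)
                if strand == "-":
                    planted = revcomp(motif.decode()).encode()
                else:
                    planted = motif
                footprint = len(planted) + 2 * _PLANT_BUFFER
                slot_start = tss - 900 + k * slot
                off = int(rng.integers(0, slot - footprint + 1))
                a = slot_start + off
                buf = _AT[rng.integers(0, 2, 2 * _PLANT_BUFFER)]
                seq[a : a + _PLANT_BUFFER] = buf[:_PLANT_BUFFER]
                start = a + _PLANT_BUFFER
                seq[start : start + len(planted)] = np.frombuffer(planted, dtype=np.uint8)
                seq[start + len(planted) : a + footprint] = buf[_PLANT_BUFFER:]
                pqs_rows.append(
                    {"chrom": chrom, "start": start, "end": start + len(planted),
                     "strand": strand, "gene_idx": gene_idx}
                )
            gene_idx += 1
        genome[chrom] = seq.tobytes().decode()
    pqs_cols = ["chrom", "start", "end", "strand", "gene_idx"]
    pqs_df = (
        pd.DataFrame(pqs_rows).sort_values(["chrom", "start"]).reset_index(drop=True)
        if pqs_rows
        else pd.DataFrame(columns=pqs_cols)
    )
    truth = SimTruth(genes=pd.DataFrame(gene_rows), pqs=pqs_df)
    return genome, anchors, truth


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------


def _cpg_positions(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def simulate_methylome(
    genome: dict[str, str], truth: SimTruth, config: SimConfig, seed: int
) -> MethylCalls:
    """Promoter-stratified bisulfite calls around every TSS.

    Each promoter is hyper- or hypomethylated; per-CpG true levels are Beta
    draws around the state mean, read depth is Poisson, methylated counts
    Binomial.  In the KO condition every true level is multiplied by
    ``ko_meth_scale`` (states, CpG identities and Beta draws are shared with
    WT so the knockout is a pure level rescaling).  Calls are emitted for
    CpGs within ``meth_window`` of a TSS; covered sites only.

    Updates ``truth`` in place with per-gene states, per-CpG true levels and
    the per-PQS mean true methylation (``true_meth``, on the 0-1 scale).
    """
    rng_struct = _rng(seed, _STAGE_METH)
    rng_counts = _rng(seed, _STAGE_METH, config.condition)
    genes = truth.genes
    hyper = rng_struct.random(len(genes)) < config.promoter_hyper_fraction
    truth.genes = genes = genes.assign(hyper=hyper)

    c = config.level_concentration
    frames = []
    for chrom, grp in genes.groupby("chrom", sort=False):
        all_cpg = _cpg_positions(genome[chrom])
        tss = grp.tss.to_numpy()
        lo = np.searchsorted(all_cpg, tss - config.meth_window)
        hi = np.searchsorted(all_cpg, tss + config.meth_window)
        pos_parts, level_parts = [], []
        for g_hyper, i, j in zip(grp.hyper.to_numpy(), lo, hi):
            pos = all_cpg[i:j]
            mu = config.hyper_level if g_hyper else config.hypo_level
            level = rng_struct.beta(c * mu, c * (1 - mu), size=len(pos))
            pos_parts.append(pos)
            level_parts.append(level)
        pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
        level = np.concatenate(level_parts) if level_parts else np.empty(0)
        # promoters are disjoint (spacing >= 4000 > 2*meth_window) -> no dups
        if config.condition == "KO":
            level = level * config.ko_meth_scale
        truth.cpg_positions[chrom] = pos
        truth.cpg_true_level[chrom] = level
        cov = rng_counts.poisson(config.coverage_mean, size=len(pos))
        n_meth = rng_counts.binomial(cov, level)
        covered = cov > 0
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos[covered], "strand": "+",
                 "n_meth": n_meth[covered], "n_total": cov[covered]}
            )
        )
    calls = MethylCalls(pd.concat(frames, ignore_index=True))

    # per-PQS mean true methylation over the CpGs inside each PQS
    true_meth = np.full(len(truth.pqs), np.nan)
    for chrom, grp in truth.pqs.groupby("chrom", sort=False):
        pos = truth.cpg_positions.get(chrom, np.empty(0, dtype=np.int64))
        level = truth.cpg_true_level.get(chrom, np.empty(0))
        cum = np.concatenate([[0.0], np.cumsum(level)])
        i = np.searchsorted(pos, grp.start.to_numpy())
        j = np.searchsorted(pos, grp.end.to_numpy() - 1)
        n = j - i
        with np.errstate(invalid="ignore"):
            m = np.where(n > 0, (cum[j] - cum[i]) / np.maximum(n, 1), np.nan)
        true_meth[grp.index.to_numpy()] = m
    truth.pqs = truth.pqs.assign(true_meth=true_meth)
    return calls


# ---------------------------------------------------------------------------
# Accessibility and G4 signal
# ---------------------------------------------------------------------------


def _bin_track(chrom_rates: dict[str, np.ndarray], rng, bin_size: int) -> SignalTrack:
    """Poisson counts per bin from per-bin rate arrays, zero bins dropped."""
    runs = {}
    for chrom, rates in chrom_rates.items():
        counts = rng.poisson(rates)
        idx = np.flatnonzero(counts > 0)
        runs[chrom] = (idx * bin_size, (idx + 1) * bin_size, counts[idx].astype(float))
    return SignalTrack(runs)


def _chrom_lengths(truth: SimTruth, config: SimConfig) -> dict[str, int]:
    sizes = truth.genes.groupby("chrom", sort=False).size()
    return {c: int(n * config.gene_spacing) for c, n in sizes.items()}


def simulate_atac(
    truth: SimTruth, config: SimConfig, seed: int
) -> tuple[SignalTrack, PeakSet]:
    """Accessibility track and peak set.

    A configured fraction of promoters is open; accessibility a in (0, 1) is
    Beta-distributed (high for open, low for closed promoters) and recorded
    in the truth table.  Every promoter receives a plateau of Poisson rate
    ``atac_amplitude * a`` over TSS +- ``atac_halfwidth`` on top of the
    background — the bulk ATAC signal tracks accessibility continuously —
    while peaks are exactly the open-promoter windows (where the noiseless
    rate rises well above background).  Accessibility and open/closed
    states are structural (condition-independent); only counting noise
    differs between conditions.
    """
    rng_struct = _rng(seed, _STAGE_ATAC)
    rng_noise = _rng(seed, _STAGE_ATAC, config.condition)
    genes = truth.genes
    is_open = rng_struct.random(len(genes)) < config.open_fraction
    a = np.where(
        is_open,
        rng_struct.beta(6.0, 2.0, size=len(genes)),
        rng_struct.beta(2.0, 6.0, size=len(genes)),
    )
    truth.genes = genes = genes.assign(open=is_open, accessibility=a)

    lengths = _chrom_lengths(truth, config)
    bs = config.bin_size
    rates = {c: np.full(n // bs, config.atac_background) for c, n in lengths.items()}
    peaks = []
    for row in genes.itertuples():
        lo = (row.tss - config.atac_halfwidth) // bs
        hi = (row.tss + config.atac_halfwidth) // bs
        # the plateau tracks accessibility continuously; only open promoters
        # rise far enough above background to be called as peaks
        rates[row.chrom][lo:hi] += config.atac_amplitude * row.accessibility
        if not row.open:
            continue
        peaks.append(
            GenomeInterval(
                row.chrom,
                row.tss - config.atac_halfwidth,
                row.tss + config.atac_halfwidth,
                ".",
                row.gene_id,
                float(row.accessibility),
            )
        )
    return _bin_track(rates, rng_noise, bs), PeakSet(peaks)


def formation_probability(m, a, config: SimConfig) -> np.ndarray:
    """Logistic G4 formation probability from methylation m and accessibility a."""
    return _sigmoid(config.beta0 + config.beta_m * (1.0 - np.asarray(m)) + config.beta_a * np.asarray(a))


def simulate_g4(
    truth: SimTruth, config: SimConfig, seed: int
) -> tuple[SignalTrack, PeakSet, SignalTrack]:
    """G4 coverage track, peak set and matched IgG background track.

    Per PQS the formation probability follows the logistic model; the bulk
    coverage bump height is ``g4_amplitude * p`` times log-normal noise
    (a population of cells averages over the Bernoulli formation events,
    which are drawn separately and stored in the truth table).  The IgG
    track is background only.  PQSs whose noiseless bump height reaches
    ``g4_peak_min`` contribute a peak (bump footprint, merged).
    """
    if "true_meth" not in truth.pqs.columns:
        raise ValueError("simulate_methylome must run before simulate_g4")
    if "accessibility" not in truth.genes.columns:
        raise ValueError("simulate_atac must run before simulate_g4")
    rng = _rng(seed, _STAGE_G4, config.condition)
    pqs = truth.pqs
    m = pqs.true_meth.to_numpy()
    m = np.where(np.isnan(m), 0.5, m)
    a = truth.genes.accessibility.to_numpy()[pqs.gene_idx.to_numpy()]
    p = formation_probability(m, a, config)
    formed = rng.random(len(pqs)) < p
    amp = config.g4_amplitude * p * rng.lognormal(0.0, config.g4_amp_sigma, size=len(pqs))
    truth.pqs = pqs = pqs.assign(p_form=p, formed=formed, amplitude=amp)

    lengths = _chrom_lengths(truth, config)
    bs = config.bin_size
    rates = {c: np.full(n // bs, config.g4_background) for c, n in lengths.items()}
    peak_ivs = []
    pad = config.g4_bump_pad
    for row in pqs.itertuples():
        lo = max((row.start - pad) // bs, 0)
        hi = min((row.end + pad) // bs + 1, len(rates[row.chrom]))
        rates[row.chrom][lo:hi] += row.amplitude
        if row.amplitude >= config.g4_peak_min:
            peak_ivs.append(
                GenomeInterval(row.chrom, max(row.start - pad, 0), row.end + pad)
            )
    g4_track = _bin_track(rates, rng, bs)
    igg = _bin_track(
        {c: np.full(n // bs, config.g4_background) for c, n in lengths.items()}, rng, bs
    )
    peaks = PeakSet(peak_ivs).merged() if peak_ivs else PeakSet()
    return g4_track, peaks, igg


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def gene_occupancy(truth: SimTruth) -> np.ndarray:
    """Mean G4 formation probability over each gene's promoter PQSs."""
    if "p_form" not in truth.pqs.columns:
        raise ValueError("simulate_g4 must run before computing occupancy")
    occ = np.zeros(len(truth.genes))
    grouped = truth.pqs.groupby("gene_idx")["p_form"].mean()
    occ[grouped.index.to_numpy()] = grouped.to_numpy()
    return occ


def simulate_expression(
    truth_wt: SimTruth,
    truth_ko: SimTruth,
    config: SimConfig,
    seed: int,
    occ_wt: np.ndarray | None = None,
    occ_ko: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate negative-binomial counts and a naive WT-vs-KO DE table.

    The expression mean of gene g is base_g * (1 + effect * occupancy_g),
    with occupancy the promoter G4 formation probability averaged over the
    gene's PQSs in each condition.  The DE table carries the empirical
    log2 fold change (KO vs WT, +0.5 pseudocount) and a per-gene Student's t
    p-value on log2(count+1) across replicates — deliberately a naive
    pipeline, not a shrinkage-based DE method.  The expected log2FC implied
    by the latent occupancies is included for recovery tests.
    """
    rng = _rng(seed, _STAGE_EXPR)
    genes = truth_wt.genes
    n = len(genes)
    if occ_wt is None:
        occ_wt = gene_occupancy(truth_wt)
    if occ_ko is None:
        occ_ko = gene_occupancy(truth_ko)
    base = rng.lognormal(np.log(config.expr_base_mean), config.expr_base_sigma, size=n)
    mu_wt = base * (1.0 + config.expr_effect * occ_wt)
    mu_ko = base * (1.0 + config.expr_effect * occ_ko)
    r = 1.0 / config.expr_dispersion
    reps = config.n_replicates

    def draw(mu):
        return rng.negative_binomial(r, r / (r + mu[:, None]), size=(n, reps))

    cw, ck = draw(mu_wt), draw(mu_ko)
    counts = pd.DataFrame(
        np.hstack([cw, ck]),
        columns=[f"WT_{i+1}" for i in range(reps)] + [f"KO_{i+1}" for i in range(reps)],
    )
    counts.insert(0, "gene_id", genes.gene_id.to_numpy())

    lw, lk = np.log2(cw + 1.0), np.log2(ck + 1.0)
    res = stats.ttest_ind(lk, lw, axis=1, equal_var=True)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    log2fc = np.log2((ck.mean(axis=1) + 0.5) / (cw.mean(axis=1) + 0.5))
    expected = np.log2(
        (1.0 + config.expr_effect * occ_ko) / (1.0 + config.expr_effect * occ_wt)
    )
    de = pd.DataFrame(
        {
            "gene_id": genes.gene_id.to_numpy(),
            "log2fc": log2fc,
            "p_value": pvals,
            "expected_log2fc": expected,
        }
    )
    return counts, de


# ---------------------------------------------------------------------------
# Bisulfite conversion
# ---------------------------------------------------------------------------


def bisulfite_convert(sequence: str, methylated_positions: set[int]) -> str:
    """In-silico bisulfite conversion at 100% efficiency.

    Every unmethylated C reads as T (uracil after PCR); methylated Cs are
    protected and remain C.  Positions must index cytosines.
    """
    chars = list(sequence)
    for p in methylated_positions:
        if p < 0 or p >= len(chars) or chars[p].upper() != "C":
            raise ValueError(f"position {p} is not a cytosine")
    for i, ch in enumerate(chars):
        if i in methylated_positions:
            continue
        if ch == "C":
            chars[i] = "T"
        elif ch == "c":
            chars[i] = "t"
    return "".join(chars)


# ---------------------------------------------------------------------------
# Whole-dataset convenience and calibration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimConfig
    seed: int
    genome: dict[str, str]
    anchors: list[TranscriptAnchor]
    truth: SimTruth
    calls: MethylCalls
    atac_track: SignalTrack
    atac_peaks: PeakSet
    g4_track: SignalTrack
    g4_peaks: PeakSet
    igg_track: SignalTrack

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_dataset(config: SimConfig, seed: int) -> SimulatedDataset:
    """Run every generator stage in order and bundle the outputs."""
    genome, anchors, truth = generate_genome(config, seed)
    calls = simulate_methylome(genome, truth, config, seed)
    atac_track, atac_peaks = simulate_atac(truth, config, seed)
    g4_track, g4_peaks, igg = simulate_g4(truth, config, seed)
    return SimulatedDataset(
        config=config,
        seed=seed,
        genome=genome,
        anchors=anchors,
        truth=truth,
        calls=calls,
        atac_track=atac_track,
        atac_peaks=atac_peaks,
        g4_track=g4_track,
        g4_peaks=g4_peaks,
        igg_track=igg,
    )


def calibrate_coupling(
    target_r: float,
    config: SimConfig,
    seeds: list[int],
    beta_lo: float = 0.0,
    beta_hi: float = 4.0,
    tol: float = 0.02,
    max_iter: int = 20,
) -> tuple[float, float]:
    """Bisection on beta_a until the simulated G4-ATAC Pearson hits target_r.

    At each candidate beta_a the G4 layer is re-simulated on cached
    genome/methylome/accessibility realizations for every seed (common
    random numbers, so the response curve is smooth and monotone over the
    bracket) and the Pearson correlation of the filtered PQS joint table is
    averaged over seeds.  Returns (beta_a, achieved mean R).  Raises if
    target_r is outside the bracketed response range.
    """
    from .integrate import build_pqs_joint_table, pearson_g4_atac
    from .pqs_scan import annotate_cpg_all, scan_canonical_pqs

    if not 0 < target_r < 1:
        raise ValueError("target_r must be in (0, 1)")

    cohorts = []
    for s in seeds:
        genome, anchors, truth = generate_genome(config, s)
        calls = simulate_methylome(genome, truth, config, s)
        atac_track, atac_peaks = simulate_atac(truth, config, s)
        pqs = []
        for chrom in sorted(genome):
            pqs.extend(scan_canonical_pqs(genome[chrom], chrom))
        pqs = annotate_cpg_all(pqs, genome)
        cohorts.append((truth, calls, atac_track, atac_peaks, pqs, s))

    def evaluate(beta_a: float) -> float:
        cfg = config.replace(beta_a=beta_a)
        rs = []
        for truth, calls, atac_track, atac_peaks, pqs, s in cohorts:
            g4_track, g4_peaks, _ = simulate_g4(truth, cfg, s)
            table = build_pqs_joint_table(
                pqs, g4_peaks, g4_track, atac_peaks, atac_track, calls
            )
            rs.append(pearson_g4_atac(table))
        return float(np.mean(rs))

    r_lo, r_hi = evaluate(beta_lo), evaluate(beta_hi)
    if not (min(r_lo, r_hi) <= target_r <= max(r_lo, r_hi)):
        raise ValueError(
            f"target R={target_r} unreachable: bracket R({beta_lo})={r_lo:.3f}, "
            f"R({beta_hi})={r_hi:.3f}"
        )
    increasing = r_hi >= r_lo
    best = min([(abs(r_lo - target_r), beta_lo, r_lo), (abs(r_hi - target_r), beta_hi, r_hi)])
    for _ in range(max_iter):
        mid = 0.5 * (beta_lo + beta_hi)
        r_mid = evaluate(mid)
        if abs(r_mid - target_r) < best[0]:
            best = (abs(r_mid - target_r), mid, r_mid)
        if abs(r_mid - target_r) <= tol:
            return mid, r_mid
        if (r_mid < target_r) == increasing:
            beta_lo = mid
        else:
            beta_hi = mid
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Dataset writers (the formats the analysis modules read)
# ---------------------------------------------------------------------------


def write_dataset(ds: SimulatedDataset, out_dir) -> dict[str, str]:
    """Write FASTA, anchors, calls, tracks, peaks, truth and config files."""
    from pathlib import Path

    from .core_tracks import write_bed, write_bedgraph
    from .methylome import write_anchors_tsv
    from .pqs_scan import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = ds.config.condition.lower()
    paths = {
        "fasta": out / "genome.fa",
        "anchors": out / "tss.tsv",
        "calls": out / f"meth_calls_{tag}.tsv",
        "atac_track": out / f"atac_{tag}.bedgraph",
        "atac_peaks": out / f"atac_peaks_{tag}.bed",
        "g4_track": out / f"g4_{tag}.bedgraph",
        "g4_peaks": out / f"g4_peaks_{tag}.bed",
        "igg_track": out / f"igg_{tag}.bedgraph",
        "truth_genes": out / f"truth_genes_{tag}.tsv",
        "truth_pqs": out / f"truth_pqs_{tag}.tsv",
        "config": out / f"sim_config_{tag}.json",
    }
    write_fasta(ds.genome, paths["fasta"])
    write_anchors_tsv(ds.anchors, paths["anchors"])
    ds.calls.to_tsv(paths["calls"])
    write_bedgraph(ds.atac_track, paths["atac_track"])
    write_bed(ds.atac_peaks, paths["atac_peaks"])
    write_bedgraph(ds.g4_track, paths["g4_track"])
    write_bed(ds.g4_peaks, paths["g4_peaks"])
    write_bedgraph(ds.igg_track, paths["igg_track"])
    ds.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    ds.truth.pqs.to_csv(paths["truth_pqs"], sep="\t", index=False)
    ds.config.to_json(paths["config"])
    return {k: str(v) for k, v in paths.items()}
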