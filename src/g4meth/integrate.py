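"""Joint PQS annotation across G4, accessibility and methylation layers.

The central object is the PQS joint table: one row per PQS carrying its mean
G4 and ATAC signal, whether it sits under a G4 peak, whether it overlaps an
ATAC peak (open chromatin), and its CpG methylation state (high iff the mean
site level over its CpGs exceeds 50%).  Downstream summaries — the 2x2
accessibility x methylation stratification, the G4-ATAC Pearson coupling,
per-chromosome knockout/wild-type log2 ratios, the non-differential ATAC
peak selection, the differential-expression filter and the promoter-G4
linkage — all read from this table or from anchored matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_tracks import GenomeInterval, PeakSet, SignalTrack, mean_signal_many, overlaps
from .meta_signal import AnchoredMatrix
from .methylome import MethylCalls, TranscriptAnchor, pqs_methylation_state

JOINT_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "n_cpg",
    "has_g4_peak",
    "g4_signal",
    "atac_signal",
    "open",
    "meth_state",
    "meth_level",
]

STRATA = [
    "all",
    "open",
    "closed",
    "hypo",
    "hyper",
    "open_hypo",
    "open_hyper",
    "closed_hypo",
    "closed_hyper",
]

PAIRED_TESTS = {
    "open_vs_closed": ("open", "closed"),
    "hypo_vs_hyper": ("hypo", "hyper"),
    "open_hypo_vs_open_hyper": ("open_hypo", "open_hyper"),
    "closed_hypo_vs_closed_hyper": ("closed_hypo", "closed_hyper"),
}


def build_pqs_joint_table(
    pqs_list,
    g4_peaks: PeakSet,
    g4_track: SignalTrack,
    atac_peaks: PeakSet,
    atac_track: SignalTrack,
    calls: MethylCalls,
    require_g4_and_cpg: bool = True,
    meth_threshold_pct: float = 50.0,
    meth_mode: str = "mean",
) -> pd.DataFrame:
    """Annotate every PQS across the three layers.

    With ``require_g4_and_cpg`` the table is filtered to PQSs under a G4 peak
    that contain at least one CpG (the promoter-PQS analysis set); rows are
    sorted by (chrom, start, strand).
    """
    if not pqs_list:
        return pd.DataFrame(columns=JOINT_COLUMNS)
    ivset = PeakSet([p.interval for p in pqs_list])
    has_peak = overlaps(ivset, g4_peaks)
    is_open = overlaps(ivset, atac_peaks)

    g4_sig = np.zeros(len(pqs_list))
    atac_sig = np.zeros(len(pqs_list))
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(pqs_list):
        by_chrom.setdefault(p.interval.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        s = np.array([pqs_list[i].interval.start for i in idx], dtype=np.int64)
        e = np.array([pqs_list[i].interval.end for i in idx], dtype=np.int64)
        g4_sig[idx] = mean_signal_many(g4_track, chrom, s, e)
        atac_sig[idx] = mean_signal_many(atac_track, chrom, s, e)

    states, levels = [], []
    for p in pqs_list:
        st, lv = pqs_methylation_state(p, calls, meth_threshold_pct, meth_mode)
        states.append(st)
        levels.append(np.nan if lv is None else lv)

    df = pd.DataFrame(
        {
            "chrom": [p.interval.chrom for p in pqs_list],
            "start": [p.interval.start for p in pqs_list],
            "end": [p.interval.end for p in pqs_list],
            "strand": [p.interval.strand for p in pqs_list],
            "n_cpg": [len(p.cpg_positions) for p in pqs_list],
            "has_g4_peak": has_peak,
            "g4_signal": g4_sig,
            "atac_signal": atac_sig,
            "open": is_open,
            "meth_state": states,
            "meth_level": levels,
        }
    )
    if require_g4_and_cpg:
        df = df[df.has_g4_peak & (df.n_cpg > 0)]
    return df.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(
        drop=True
    )


def pearson_g4_atac(table: pd.DataFrame, log_transform: bool = False) -> float:
    """Sample Pearson correlation of per-PQS (G4 signal, ATAC signal).

    Raw signal values by default; ``log_transform`` applies log2(1+x) to
    both columns first.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 PQSs for a correlation")
    x = table["atac_signal"].to_numpy(float)
    y = table["g4_signal"].to_numpy(float)
    if log_transform:
        x, y = np.log2(1 + x), np.log2(1 + y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class StrataSummary:
    """Mean G4 signal per stratum with pairwise Student's t comparisons."""

    summary: pd.DataFrame  # index: stratum; columns: n, mean, sem
    tests: dict[str, tuple[float, float] | None]  # name -> (t, p) or None


def _stratum_masks(table: pd.DataFrame) -> dict[str, np.ndarray]:
    is_open = table["open"].to_numpy(bool)
    hypo = (table["meth_state"] == "low").to_numpy()
    hyper = (table["meth_state"] == "high").to_numpy()
    return {
        "all": np.ones(len(table), dtype=bool),
        "open": is_open,
        "closed": ~is_open,
        "hypo": hypo,
        "hyper": hyper,
        "open_hypo": is_open & hypo,
        "open_hyper": is_open & hyper,
        "closed_hypo": ~is_open & hypo,
        "closed_hyper": ~is_open & hyper,
    }


def stratified_summary(
    table: pd.DataFrame,
    equal_var: bool = True,
    alternative: str = "two-sided",
) -> StrataSummary:
    """G4 signal by chromatin accessibility and methylation strata.

    PQSs with an undefined methylation state contribute to the all/open/
    closed strata but to none of the methylation strata.  Comparisons with
    an empty side are reported as unavailable (None).
    """
    masks = _stratum_masks(table)
    sig = table["g4_signal"].to_numpy(float)
    rows = []
    for name in STRATA:
        vals = sig[masks[name]]
        n = len(vals)
        mean = float(np.mean(vals)) if n else np.nan
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"stratum": name, "n": n, "mean": mean, "sem": sem})
    summary = pd.DataFrame(rows).set_index("stratum")
    tests: dict[str, tuple[float, float] | None] = {}
    for name, (a, b) in PAIRED_TESTS.items():
        va, vb = sig[masks[a]], sig[masks[b]]
        if len(va) < 2 or len(vb) < 2:
            tests[name] = None
            continue
        res = stats.ttest_ind(va, vb, equal_var=equal_var, alternative=alternative)
        tests[name] = (float(res.statistic), float(res.pvalue))
    return StrataSummary(summary=summary, tests=tests)


def nondifferential_atac_peaks(
    common_peaks: PeakSet,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    m_cutoff: float = 1.0,
) -> PeakSet:
    """Select peaks with similar signal in two conditions (MAnorm-style).

    M = log2((a+1)/(b+1)) per common peak, rescaled by subtracting the
    median M (absorbing global depth differences); peaks with
    |M_rescaled| <= m_cutoff are retained, carrying M_rescaled as score.
    This is a median-rescaling simplification of the MAnorm common-peak
    normalization, not its robust regression model.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if len(common_peaks) != len(counts_a) or len(common_peaks) != len(counts_b):
        raise ValueError("counts must align with common_peaks")
    if len(common_peaks) == 0:
        return PeakSet()
    m = np.log2((counts_a + 1) / (counts_b + 1))
    m_rescaled = m - np.median(m)
    kept = []
    for iv, mi in zip(common_peaks, m_rescaled):
        if abs(mi) <= m_cutoff:
            kept.append(
                GenomeInterval(iv.chrom, iv.start, iv.end, iv.strand, iv.name, float(mi))
            )
    return PeakSet(kept)


def chrom_log2_ratio(
    track_ko: SignalTrack, track_wt: SignalTrack, pseudo: float = 1.0
) -> dict[str, float]:
    """Per-chromosome log2 of total KO vs WT signal (area under each track).

    Both tracks are expected background-subtracted and depth-normalized.
    Chromosomes absent from both tracks are omitted.
    """
    chroms = sorted(set(track_ko.chroms()) | set(track_wt.chroms()))
    return {
        c: float(np.log2((track_ko.total(c) + pseudo) / (track_wt.total(c) + pseudo)))
        for c in chroms
    }


def de_filter(
    table: pd.DataFrame, p_max: float = 0.05, lfc_min: float = 1.0
) -> tuple[list[str], list[str]]:
    """Differential-expression filter with strict inequalities.

    up: p < p_max and log2fc > lfc_min; down: p < p_max and log2fc < -lfc_min.
    A gene at exactly |log2fc| = lfc_min is excluded.
    """
    for col in ("gene_id", "log2fc", "p_value"):
        if col not in table.columns:
            raise ValueError(f"DE table missing column {col}")
    if ((table.p_value < 0) | (table.p_value > 1)).any():
        raise ValueError("p_value outside [0, 1]")
    sig = table.p_value < p_max
    up = table.loc[sig & (table.log2fc > lfc_min), "gene_id"].tolist()
    down = table.loc[sig & (table.log2fc < -lfc_min), "gene_id"].tolist()
    return up, down


@dataclass
class PromoterG4Link:
    """Per-gene promoter G4 change between conditions for a gene cohort."""

    per_gene: pd.DataFrame  # gene_id, mean_wt, mean_ko, delta
    n_resolved: int
    n_dropped: int
    paired_t: float
    paired_p: float

    @property
    def mean_delta(self) -> float:
        return float(self.per_gene["delta"].mean())


def promoter_g4_link(
    up_genes: list[str],
    anchors: list[TranscriptAnchor],
    matrix_wt: AnchoredMatrix,
    matrix_ko: AnchoredMatrix,
) -> PromoterG4Link:
    """Promoter (TSS +- flank) mean G4 per condition for a set of genes.

    Genes without a matrix row (no defined TSS window) are dropped and
    counted.  The cohort-level comparison is a paired Student's t on the
    per-gene KO - WT differences.
    """
    if [a.transcript_id for a in matrix_wt.anchors] != [
        a.transcript_id for a in matrix_ko.anchors
    ]:
        raise ValueError("WT and KO matrices must share the same anchors")
    row_by_gene: dict[str, int] = {}
    for i, a in enumerate(matrix_wt.anchors):
        row_by_gene.setdefault(a.gene_id, i)
    rows, dropped = [], 0
    wt_means = matrix_wt.row_means()
    ko_means = matrix_ko.row_means()
    for g in up_genes:
        i = row_by_gene.get(g)
        if i is None:
            dropped += 1
            continue
        rows.append(
            {
                "gene_id": g,
                "mean_wt": float(wt_means[i]),
                "mean_ko": float(ko_means[i]),
                "delta": float(ko_means[i] - wt_means[i]),
            }
        )
    if not rows:
        raise ValueError("no gene in the cohort resolves to a promoter window")
    per_gene = pd.DataFrame(rows)
    if len(per_gene) > 1 and per_gene["delta"].std(ddof=1) > 0:
        res = stats.ttest_rel(per_gene["mean_ko"], per_gene["mean_wt"])
        t, p = float(res.statistic), float(res.pvalue)
    else:
        t, p = np.nan, np.nan
    return PromoterG4Link(
        per_gene=per_gene,
        n_resolved=len(per_gene),
        n_dropped=dropped,
        paired_t=t,
        paired_p=p,
    )


def promoter_fraction(peaks: PeakSet, anchors: list[TranscriptAnchor], flank: int = 1000) -> float:
    """Share of peaks overlapping any promoter window (TSS +- flank)."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    windows = PeakSet(
        [GenomeInterval(a.chrom, max(a.tss - flank, 0), a.tss + flank) for a in anchors]
    )
    return float(np.mean(overlaps(peaks, windows)))
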