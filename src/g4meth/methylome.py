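"""Per-site and per-window CpG methylation levels and hyper/hypo selection.

The atom is one cytosine's bisulfite read counts (methylated / total); the
site methylation level is 100 * n_meth / n_total, in percent.  Window levels
are unweighted means over covered sites, matching the convention of
averaging per-cytosine methylation ratios within a region.  Strands of a
CpG dyad are not merged: calls are used exactly as provided, at the
granularity of a methratio-style extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_tracks import GenomeInterval

CALL_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_total"]


@dataclass(frozen=True)
class CpGCall:
    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError("need 0 <= n_meth <= n_total")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")


@dataclass(frozen=True)
class TranscriptAnchor:
    """A transcript's TSS used to anchor promoter windows."""

    gene_id: str
    transcript_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")

    def window(self, flank: int) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.tss - flank, self.tss + flank, self.strand)


@dataclass
class MethylSelection:
    """Hyper- and hypomethylated transcripts after per-gene deduplication."""

    hyper: list[TranscriptAnchor]
    hypo: list[TranscriptAnchor]
    levels: dict[str, float]  # transcript_id -> window methylation percent


def site_methylation_level(call: CpGCall) -> float:
    """100 * n_meth / n_total; a zero-coverage site has no level (error)."""
    if call.n_total == 0:
        raise ValueError("site with n_total = 0 has no methylation level")
    return 100.0 * call.n_meth / call.n_total


class MethylCalls:
    """Column-oriented container for many CpG calls with fast window queries.

    Wraps a DataFrame with columns chrom, pos, strand, n_meth, n_total.
    Zero-coverage rows are carried but excluded from every level computation.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        missing = [c for c in CALL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing call columns: {missing}")
        df = df[CALL_COLUMNS].copy()
        if ((df.n_meth < 0) | (df.n_meth > df.n_total)).any():
            raise ValueError("need 0 <= n_meth <= n_total in every row")
        self.df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        covered = self.df[self.df.n_total > 0].copy()
        covered["level"] = 100.0 * covered.n_meth / covered.n_total
        for chrom, grp in covered.groupby("chrom", sort=False):
            pos = grp.pos.to_numpy(dtype=np.int64)
            lv = grp.level.to_numpy(dtype=np.float64)
            cum = np.concatenate([[0.0], np.cumsum(lv)])
            self._index[chrom] = (pos, lv, cum)

    @classmethod
    def from_calls(cls, calls) -> "MethylCalls":
        return cls(pd.DataFrame([c.__dict__ for c in calls], columns=CALL_COLUMNS))

    @classmethod
    def read_tsv(cls, path) -> "MethylCalls":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.df)

    # -- window queries ------------------------------------------------------

    def window_stats(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(covered-site count, mean site level) for many half-open windows."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._index:
            return np.zeros(len(starts), dtype=np.int64), np.full(len(starts), np.nan)
        pos, _, cum = self._index[chrom]
        i = np.searchsorted(pos, starts, side="left")
        j = np.searchsorted(pos, ends, side="left")
        n = j - i
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (cum[j] - cum[i]) / np.maximum(n, 1), np.nan)
        return n, mean

    def levels_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Site level at exact positions (NaN where uncovered/absent)."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._index:
            return np.full(len(positions), np.nan)
        pos, lv, _ = self._index[chrom]
        i = np.searchsorted(pos, positions, side="left")
        i_c = np.clip(i, 0, max(len(pos) - 1, 0))
        hit = (i < len(pos)) & (pos[i_c] == positions)
        return np.where(hit, lv[i_c], np.nan)


def window_methylation_level(
    calls: MethylCalls, region: GenomeInterval, min_sites: int = 1
) -> float | None:
    """Unweighted mean site level over covered CpGs in the region.

    Returns None (undefined) when fewer than min_sites covered CpGs fall in
    the region.
    """
    n, mean = calls.window_stats(
        region.chrom, np.array([region.start]), np.array([region.end])
    )
    if n[0] < min_sites:
        return None
    return float(mean[0])


def select_hyper_hypo(
    anchors: list[TranscriptAnchor],
    calls: MethylCalls,
    flank: int = 1000,
    top_n: int = 10000,
    min_sites: int = 1,
) -> MethylSelection:
    """Rank transcripts by promoter (TSS +- flank) methylation; pick extremes.

    The top_n highest-level transcripts form the hypermethylated list and the
    top_n lowest the hypomethylated list; within each list only the most
    extreme-ranked transcript per gene is kept.  Ties are broken by
    lexicographic transcript_id.  With fewer than 2*top_n rankable
    transcripts the lists shrink (floor(n/2) each) so they stay disjoint.
    """
    rows = []
    by_chrom: dict[str, list[TranscriptAnchor]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom, group in by_chrom.items():
        starts = np.array([a.tss - flank for a in group], dtype=np.int64)
        ends = np.array([a.tss + flank for a in group], dtype=np.int64)
        if np.any(starts < 0):
            raise ValueError("anchor window extends past the chromosome start")
        n, mean = calls.window_stats(chrom, starts, ends)
        for a, ni, mi in zip(group, n, mean):
            if ni >= min_sites:
                rows.append((a, float(mi)))
    if not rows:
        raise ValueError("no transcript has a defined methylation level")
    if len(rows) < 2 * top_n:
        warnings.warn(
            f"only {len(rows)} rankable transcripts for top_n={top_n}; "
            "shrinking both lists to keep them disjoint"
        )
        top_n = len(rows) // 2
    levels = {a.transcript_id: lv for a, lv in rows}

    def dedup(ordered: list[TranscriptAnchor]) -> list[TranscriptAnchor]:
        seen, out = set(), []
        for a in ordered:
            if a.gene_id not in seen:
                seen.add(a.gene_id)
                out.append(a)
        return out

    desc = sorted(rows, key=lambda r: (-r[1], r[0].transcript_id))
    asc = sorted(rows, key=lambda r: (r[1], r[0].transcript_id))
    hyper = dedup([a for a, _ in desc[:top_n]])
    hypo = dedup([a for a, _ in asc[:top_n]])
    return MethylSelection(hyper=hyper, hypo=hypo, levels=levels)


def pqs_methylation_state(
    pqs,
    calls: MethylCalls,
    threshold_pct: float = 50.0,
    mode: str = "mean",
) -> tuple[str, float | None]:
    """Methylation state of a PQS from the calls covering its CpGs.

    The level is the mean site level over the PQS's covered CpGs; the state
    is "high" iff that level strictly exceeds threshold_pct (mean exactly at
    the threshold is "low"), and "undefined" with no covered CpG.  With
    mode="any" a single covered site above the threshold makes the PQS
    "high" instead.

    A call is taken to cover the dyad at plus-strand position p when it sits
    at p (either strand) or at p+1 on the minus strand.
    """
    if mode not in ("mean", "any"):
        raise ValueError("mode must be 'mean' or 'any'")
    chrom = pqs.interval.chrom
    pos = np.asarray(pqs.cpg_positions, dtype=np.int64)
    if len(pos) == 0:
        return "undefined", None
    plus = calls.levels_at(chrom, pos)
    minus = calls.levels_at(chrom, pos + 1)
    site_levels = np.concatenate([plus[~np.isnan(plus)], minus[~np.isnan(minus)]])
    if len(site_levels) == 0:
        return "undefined", None
    level = float(np.mean(site_levels))
    if mode == "mean":
        high = level > threshold_pct
    else:
        high = bool(np.any(site_levels > threshold_pct))
    return ("high" if high else "low"), level


# ---------------------------------------------------------------------------
# Anchor I/O
# ---------------------------------------------------------------------------

ANCHOR_COLUMNS = ["gene_id", "transcript_id", "chrom", "tss", "strand"]


def read_anchors_tsv(path) -> list[TranscriptAnchor]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing anchor columns: {missing}")
    return [
        TranscriptAnchor(r.gene_id, r.transcript_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples()
    ]


def write_anchors_tsv(anchors, path) -> None:
    pd.DataFrame([a.__dict__ for a in anchors], columns=ANCHOR_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_selection_tsv(selection: MethylSelection, path) -> None:
    rows = []
    for cls, group in (("hyper", selection.hyper), ("hypo", selection.hypo)):
        for rank, a in enumerate(group, start=1):
            rows.append(
                {
                    "class": cls,
                    "rank": rank,
                    "gene_id": a.gene_id,
                    "transcript_id": a.transcript_id,
                    "chrom": a.chrom,
                    "tss": a.tss,
                    "strand": a.strand,
                    "level_pct": selection.levels[a.transcript_id],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
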