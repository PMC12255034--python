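"""Genomic intervals, sparse signal tracks, and the overlap engine.

Coordinates are 0-based half-open everywhere, matching BED and bedGraph.
A :class:`SignalTrack` stores, per chromosome, sorted non-overlapping runs of
constant non-negative signal; uncovered bases read as 0 (sparse bedGraph
convention).  A :class:`PeakSet` is an ordered collection of intervals.

Readers are gzip-transparent (a ``.gz`` suffix triggers decompression).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomeInterval:
    """A 0-based half-open genomic interval with optional name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        """True iff the two intervals share at least one base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered list of :class:`GenomeInterval` (peaks, PQSs, anchors...).

    Intervals may overlap within a set; :meth:`merged` returns the disjoint
    union per chromosome.
    """

    def __init__(self, intervals: Iterable[GenomeInterval] = ()) -> None:
        self.intervals: list[GenomeInterval] = list(intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomeInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays in input order."""
        out: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            s, e = out.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    def merged(self) -> "PeakSet":
        """Disjoint union of the intervals, sorted by (chrom, start)."""
        merged: list[GenomeInterval] = []
        for chrom in sorted({iv.chrom for iv in self.intervals}):
            ivs = sorted(
                (iv for iv in self.intervals if iv.chrom == chrom),
                key=lambda iv: (iv.start, iv.end),
            )
            cur_s, cur_e = ivs[0].start, ivs[0].end
            for iv in ivs[1:]:
                if iv.start <= cur_e:
                    cur_e = max(cur_e, iv.end)
                else:
                    merged.append(GenomeInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            merged.append(GenomeInterval(chrom, cur_s, cur_e))
        return PeakSet(merged)


class SignalTrack:
    """Per-chromosome sorted, disjoint runs of (start, end, value >= 0)."""

    def __init__(
        self, runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None
    ) -> None:
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, (s, e, v) in runs.items():
                self._add_chrom(chrom, s, e, v)

    def _add_chrom(self, chrom, starts, ends, values) -> None:
        s = np.asarray(starts, dtype=np.int64)
        e = np.asarray(ends, dtype=np.int64)
        v = np.asarray(values, dtype=np.float64)
        if not (len(s) == len(e) == len(v)):
            raise ValueError("starts/ends/values length mismatch")
        if len(s) == 0:
            return
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(s >= e):
            raise ValueError(f"{chrom}: runs with start >= end")
        if np.any(s[1:] < e[:-1]):
            raise ValueError(f"{chrom}: overlapping runs")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError(f"{chrom}: values must be finite and >= 0")
        self._runs[chrom] = (s, e, v)

    # -- introspection -------------------------------------------------------

    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) for one chromosome; empty arrays if absent."""
        if chrom in self._runs:
            return self._runs[chrom]
        z = np.empty(0, dtype=np.int64)
        return z, z, np.empty(0, dtype=np.float64)

    def total(self, chrom: str | None = None) -> float:
        """Sum of value * run-length (area under the track)."""
        if chrom is not None:
            s, e, v = self.runs(chrom)
            return float(np.sum(v * (e - s)))
        return sum(self.total(c) for c in self.chroms())

    def n_runs(self) -> int:
        return sum(len(s) for s, _, _ in self._runs.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.chroms() != other.chroms():
            return False
        for c in self.chroms():
            for a, b in zip(self.runs(c), other.runs(c)):
                if not np.array_equal(a, b):
                    return False
        return True

    def map_values(self, fn) -> "SignalTrack":
        return SignalTrack(
            {c: (s.copy(), e.copy(), fn(v)) for c, (s, e, v) in self._runs.items()}
        )

    def simplify(self, drop_zero: bool = True) -> "SignalTrack":
        """Coalesce adjacent runs of equal value; optionally drop zero runs."""
        out = {}
        for chrom, (s, e, v) in self._runs.items():
            if drop_zero:
                keep = v != 0
                s, e, v = s[keep], e[keep], v[keep]
            if len(s) == 0:
                continue
            ns, ne, nv = [s[0]], [e[0]], [v[0]]
            for i in range(1, len(s)):
                if s[i] == ne[-1] and v[i] == nv[-1]:
                    ne[-1] = e[i]
                else:
                    ns.append(s[i])
                    ne.append(e[i])
                    nv.append(v[i])
            out[chrom] = (np.array(ns), np.array(ne), np.array(nv, dtype=np.float64))
        return SignalTrack(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _is_header(line: str) -> bool:
    return line.startswith(("track", "browser", "#"))


def read_bed(path) -> PeakSet:
    """Read a BED3/BED6 file into a :class:`PeakSet` (0-based half-open)."""
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or _is_header(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from err
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomeInterval(fields[0], start, end, strand, name, score)
                )
            except ValueError as err:
                raise ValueError(f"{path} line {lineno}: {err}") from err
    return PeakSet(intervals)


def write_bed(peaks: PeakSet, path) -> None:
    with open(path, "wt") as fh:
        for iv in peaks:
            score = "." if iv.score is None else f"{iv.score:g}"
            name = iv.name if iv.name is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


def read_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph; overlapping runs or negative values error."""
    per_chrom: dict[str, tuple[list, list, list]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or _is_header(line):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path} line {lineno}: fewer than 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as err:
                raise ValueError(f"{path} line {lineno}: malformed fields") from err
            if start >= end:
                raise ValueError(f"{path} line {lineno}: start >= end")
            if value < 0:
                raise ValueError(f"{path} line {lineno}: negative value")
            s, e, v = per_chrom.setdefault(fields[0], ([], [], []))
            s.append(start)
            e.append(end)
            v.append(value)
    try:
        return SignalTrack(
            {c: (np.array(s), np.array(e), np.array(v)) for c, (s, e, v) in per_chrom.items()}
        )
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "wt") as fh:
        for chrom in track.chroms():
            s, e, v = track.runs(chrom)
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:.17g}\n")


# ---------------------------------------------------------------------------
# Normalization and arithmetic
# ---------------------------------------------------------------------------


def bpm_normalize(counts: SignalTrack, total_mapped_reads: int) -> SignalTrack:
    """Scale every value by 1e6 / total_mapped_reads (bins per million)."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    scale = 1e6 / float(total_mapped_reads)
    return counts.map_values(lambda v: v * scale)


def subtract_background(signal: SignalTrack, background: SignalTrack) -> SignalTrack:
    """Per-base max(0, signal - background); missing background reads as 0."""
    out = {}
    for chrom in signal.chroms():
        s1, e1, v1 = signal.runs(chrom)
        s2, e2, v2 = background.runs(chrom)
        if len(s2) == 0:
            out[chrom] = (s1.copy(), e1.copy(), v1.copy())
            continue
        # segment the chromosome at every boundary of either track
        bps = np.unique(np.concatenate([s1, e1, s2, e2]))
        seg_s, seg_e = bps[:-1], bps[1:]
        sig = _values_at(s1, e1, v1, seg_s)
        bg = _values_at(s2, e2, v2, seg_s)
        diff = np.maximum(0.0, sig - bg)
        keep = diff > 0
        out[chrom] = (seg_s[keep], seg_e[keep], diff[keep])
    return SignalTrack(out).simplify()


def _values_at(starts, ends, values, query) -> np.ndarray:
    """Track value at each query position (0 where uncovered)."""
    idx = np.searchsorted(starts, query, side="right") - 1
    idx_c = np.clip(idx, 0, max(len(starts) - 1, 0))
    if len(starts) == 0:
        return np.zeros(len(query))
    covered = (idx >= 0) & (query < ends[idx_c])
    return np.where(covered, values[idx_c], 0.0)


def mean_signal_many(
    track: SignalTrack, chrom: str, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Base-weighted mean of track values over many regions (vectorized).

    Uncovered bases count as 0.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if np.any(starts >= ends):
        raise ValueError("regions must have start < end")
    s, e, v = track.runs(chrom)
    if len(s) == 0:
        return np.zeros(len(starts))
    # cumulative integral of the track up to each run start
    lengths = (e - s).astype(np.float64)
    cum = np.concatenate([[0.0], np.cumsum(v * lengths)])

    def integral(x):
        idx = np.searchsorted(s, x, side="right") - 1
        idx_c = np.clip(idx, 0, len(s) - 1)
        partial = np.clip(x - s[idx_c], 0, e[idx_c] - s[idx_c]) * v[idx_c]
        return np.where(idx >= 0, cum[idx_c] + partial, 0.0)

    area = integral(ends) - integral(starts)
    return area / (ends - starts)


def mean_signal(track: SignalTrack, region: GenomeInterval) -> float:
    """Base-weighted mean of the track over one region (uncovered = 0)."""
    return float(
        mean_signal_many(
            track, region.chrom, np.array([region.start]), np.array([region.end])
        )[0]
    )


def overlaps(query: PeakSet, subject: PeakSet) -> np.ndarray:
    """Per-query boolean: does it share >= 1 base with any subject interval?

    Strand is ignored; adjacency (half-open touching) does not count.
    """
    merged = subject.merged().chrom_arrays()
    flags = np.zeros(len(query), dtype=bool)
    for i, iv in enumerate(query):
        if iv.chrom not in merged:
            continue
        ms, me = merged[iv.chrom]
        # first merged interval ending after iv.start
        j = int(np.searchsorted(me, iv.start, side="right"))
        flags[i] = j < len(ms) and ms[j] < iv.end
    return flags


def call_peaks_threshold(
    track: SignalTrack, threshold: float, min_len: int = 1, merge_gap: int = 0
) -> PeakSet:
    """Plumbing peak caller: maximal runs with value >= threshold.

    Above-threshold runs separated by <= merge_gap bases are merged; peaks
    shorter than min_len are dropped.  This is a stand-in for a statistical
    peak caller, intended for synthetic tracks only.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    peaks = []
    for chrom in track.chroms():
        s, e, v = track.runs(chrom)
        keep = v >= threshold
        if not np.any(keep):
            continue
        ks, ke = s[keep], e[keep]
        cur_s, cur_e = int(ks[0]), int(ke[0])
        intervals = []
        for i in range(1, len(ks)):
            if ks[i] - cur_e <= merge_gap:
                cur_e = int(ke[i])
            else:
                intervals.append((cur_s, cur_e))
                cur_s, cur_e = int(ks[i]), int(ke[i])
        intervals.append((cur_s, cur_e))
        for a, b in intervals:
            if b - a >= min_len:
                peaks.append(GenomeInterval(chrom, a, b))
    return PeakSet(peaks)
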