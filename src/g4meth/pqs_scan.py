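"""Canonical putative-quadruplex-sequence (PQS) detection.

A canonical PQS is four tracts of at least ``run_min_len`` consecutive
guanines separated by three loops of 1-12 arbitrary bases:
G3+ N1-12 G3+ N1-12 G3+ N1-12 G3+.  Detection is restricted to this
pattern (no bulges or mismatches); scoring models are out of scope.

Selection is greedy per strand: among all substrings matching the pattern,
the leftmost-starting (then longest) is kept, overlapping candidates are
discarded, and the scan resumes past its end.  Minus-strand PQSs are found
by scanning the reverse complement and mapping coordinates back, which makes
the scan strand-symmetric by construction.  Plus- and minus-strand PQSs may
overlap each other.

The scanner chains maximal G-runs with a small memoized search for the
longest completable match at each candidate start.  Loops may contain any of
A/C/G/T/N; N inside a G-tract is never allowed.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, replace
import numpy as np

from .core_tracks import GenomeInterval, PeakSet, _open_text

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PQSParams:
    """Canonical-pattern parameters (defaults: G3+ with 1-12 base loops)."""

    run_min_len: int = 3
    loop_min_len: int = 1
    loop_max_len: int = 12
    n_runs: int = 4

    def __post_init__(self) -> None:
        if self.run_min_len < 2:
            raise ValueError("run_min_len must be >= 2")
        if not (0 < self.loop_min_len <= self.loop_max_len):
            raise ValueError("need 0 < loop_min_len <= loop_max_len")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")

    @property
    def min_length(self) -> int:
        return self.n_runs * self.run_min_len + (self.n_runs - 1) * self.loop_min_len


@dataclass
class PQSRecord:
    """One detected PQS.

    ``sequence`` holds the plus-strand letters of the interval regardless of
    the PQS strand.  ``tract_starts`` and ``loop_lengths`` describe the match
    in PQS-strand coordinates: offset 0 is the 5' end of the PQS on its own
    strand (for a minus-strand PQS that is the genomic *end* of the interval).
    ``cpg_positions`` are plus-strand genomic positions of CpG cytosines
    inside the interval (see :func:`annotate_cpg`).
    """

    interval: GenomeInterval
    sequence: str
    tract_starts: tuple[int, ...]
    loop_lengths: tuple[int, ...]
    cpg_positions: tuple[int, ...] = ()

    @property
    def tract_lengths(self) -> tuple[int, ...]:
        out = []
        for i in range(len(self.tract_starts) - 1):
            out.append(
                self.tract_starts[i + 1] - self.tract_starts[i] - self.loop_lengths[i]
            )
        out.append(len(self.interval) - self.tract_starts[-1])
        return tuple(out)


# ---------------------------------------------------------------------------
# Single-strand scan
# ---------------------------------------------------------------------------


class _StrandScanner:
    """Greedy leftmost-longest canonical scan over one strand of a sequence."""

    def __init__(self, seq: str, params: PQSParams) -> None:
        self.seq = seq
        self.p = params
        # maximal G-runs as parallel sorted lists (rs, re)
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_g = arr == ord("G")
        padded = np.concatenate([[False], is_g, [False]])
        d = np.diff(padded.astype(np.int8))
        self.rs = np.flatnonzero(d == 1).tolist()
        self.re = np.flatnonzero(d == -1).tolist()
        self._memo: dict[tuple[int, int], tuple[int, int]] = {}

    def _gext(self, pos: int) -> int:
        """Length of the maximal G-run starting exactly at pos (0 if not G)."""
        i = bisect_right(self.rs, pos) - 1
        if i >= 0 and pos < self.re[i]:
            return self.re[i] - pos
        return 0

    def _best_end(self, pos: int, k: int) -> tuple[int, int]:
        """(max end, chosen next tract start) of a k-tract match from pos.

        Returns (-1, -1) when no match completes.  pos must be the start of a
        tract; the tract itself may be any >= run_min_len prefix of the G-run
        at pos, with leftover G absorbed into the following loop.
        """
        key = (pos, k)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        p = self.p
        g = self._gext(pos)
        if g < p.run_min_len:
            res = (-1, -1)
        elif k == 1:
            res = (pos + g, -1)
        else:
            lo = pos + p.run_min_len + p.loop_min_len
            hi = pos + g + p.loop_max_len
            best, best_ns = -1, -1
            ri = bisect_right(self.rs, lo) - 1
            if ri < 0:
                ri = 0
            while ri < len(self.rs) and self.rs[ri] <= hi:
                a = max(self.rs[ri], lo)
                b = min(self.re[ri] - p.run_min_len, hi)
                for ns in range(a, b + 1):
                    t_max = min(g, ns - pos - p.loop_min_len)
                    t_min = max(p.run_min_len, ns - pos - p.loop_max_len)
                    if t_min > t_max:
                        continue
                    e, _ = self._best_end(ns, k - 1)
                    if e > best:
                        best, best_ns = e, ns
                ri += 1
            res = (best, best_ns)
        self._memo[key] = res
        return res

    def scan(self) -> list[tuple[int, int, tuple[int, ...], tuple[int, ...]]]:
        """All greedy-selected matches as (start, end, tract_starts, loops)."""
        p = self.p
        out = []
        cursor = 0
        for ri in range(len(self.rs)):
            while True:
                start = max(self.rs[ri], cursor)
                if self.re[ri] - start < p.run_min_len:
                    break
                end, _ = self._best_end(start, p.n_runs)
                if end < 0:
                    break
                out.append(self._reconstruct(start, end))
                cursor = end
                if cursor >= self.re[ri]:
                    break
        return out

    def _reconstruct(self, start: int, end: int):
        """Trace the memoized choice path into tract offsets and loop lengths."""
        p = self.p
        tract_starts, loops = [0], []
        pos = start
        for k in range(p.n_runs, 1, -1):
            _, ns = self._memo[(pos, k)]
            t = min(self._gext(pos), ns - pos - p.loop_min_len)
            loops.append(ns - pos - t)
            tract_starts.append(ns - start)
            pos = ns
        return start, end, tuple(tract_starts), tuple(loops)


def scan_canonical_pqs(
    sequence: str, chrom: str, params: PQSParams = PQSParams()
) -> list[PQSRecord]:
    """Detect canonical PQSs on both strands of ``sequence``.

    Returns records sorted by (start, end, strand) with '+' before '-'.
    Raises ValueError on letters outside A/C/G/T/N (case-insensitive).
    """
    seq = sequence.upper()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        raise ValueError(f"illegal characters in sequence: {bad}")
    n = len(seq)
    records: list[PQSRecord] = []
    for start, end, tracts, loops in _StrandScanner(seq, params).scan():
        records.append(
            PQSRecord(
                GenomeInterval(chrom, start, end, "+"),
                seq[start:end],
                tracts,
                loops,
            )
        )
    rc = revcomp(seq)
    for start, end, tracts, loops in _StrandScanner(rc, params).scan():
        g_start, g_end = n - end, n - start
        records.append(
            PQSRecord(
                GenomeInterval(chrom, g_start, g_end, "-"),
                seq[g_start:g_end],
                tracts,
                loops,
            )
        )
    records.sort(key=lambda r: (r.interval.start, r.interval.end, r.interval.strand))
    return records


# ---------------------------------------------------------------------------
# CpG annotation and I/O
# ---------------------------------------------------------------------------


def annotate_cpg(pqs: PQSRecord, sequence: str) -> PQSRecord:
    """Record plus-strand genomic positions of CpG dinucleotides in the PQS.

    A CpG is a C immediately followed by G on the plus strand with both bases
    inside the interval; the palindromic dyad is counted once, by its
    plus-strand C.  ``sequence`` is the full plus-strand chromosome sequence
    (or any string covering the interval from position 0).
    """
    iv = pqs.interval
    if len(sequence) < iv.end:
        raise ValueError("sequence does not cover the PQS interval")
    seq = sequence.upper()
    positions = tuple(
        p
        for p in range(iv.start, iv.end - 1)
        if seq[p] == "C" and seq[p + 1] == "G"
    )
    return replace(pqs, cpg_positions=positions)


def annotate_cpg_all(pqs_list, genome: dict[str, str]) -> list[PQSRecord]:
    return [annotate_cpg(p, genome[p.interval.chrom]) for p in pqs_list]


def pqs_name(pqs: PQSRecord) -> str:
    """Compact structure label: tract lengths and loop lengths."""
    t = "-".join(map(str, pqs.tract_lengths))
    l = "-".join(map(str, pqs.loop_lengths))
    return f"PQS_t{t}_l{l}"


def write_pqs_bed(pqs_list, path) -> None:
    """BED6 output: name encodes tract/loop structure, score is the length."""
    with open(path, "wt") as fh:
        for p in pqs_list:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{pqs_name(p)}"
                f"\t{len(iv)}\t{iv.strand}\n"
            )


def write_pqs_tsv(pqs_list, path) -> None:
    """Companion table with sequence, structure and CpG positions."""
    with open(path, "wt") as fh:
        fh.write(
            "chrom\tstart\tend\tstrand\tsequence\ttract_starts\t"
            "tract_lengths\tloop_lengths\tcpg_positions\n"
        )
        for p in pqs_list:
            iv = p.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.strand,
                        p.sequence,
                        ",".join(map(str, p.tract_starts)),
                        ",".join(map(str, p.tract_lengths)),
                        ",".join(map(str, p.loop_lengths)),
                        ",".join(map(str, p.cpg_positions)),
                    ]
                )
                + "\n"
            )


def read_pqs_tsv(path) -> list[PQSRecord]:
    """Read the companion TSV written by :func:`write_pqs_tsv`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)

    def ints(s):
        return tuple(int(x) for x in str(s).split(",")) if s != "" else ()

    out = []
    for r in df.itertuples():
        out.append(
            PQSRecord(
                GenomeInterval(r.chrom, int(r.start), int(r.end), r.strand),
                r.sequence,
                ints(r.tract_starts),
                ints(r.loop_lengths),
                ints(r.cpg_positions),
            )
        )
    return out


def pqs_intervals(pqs_list) -> PeakSet:
    return PeakSet([p.interval for p in pqs_list])


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into {name: sequence}."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "wt") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
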