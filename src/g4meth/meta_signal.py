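"""TSS-anchored binned signal matrices, profiles and density ratios.

An :class:`AnchoredMatrix` holds one row per transcript anchor and one
column per fixed-width bin spanning TSS - flank .. TSS + flank (default
1 kb flanks, 10-bp bins, 200 columns).  Rows of minus-strand anchors are
orientation-flipped so that column 0 is always 1 kb upstream in the gene's
reading direction.  All heatmaps, mean profiles and hypo/hyper density
ratios are computed from this grid.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_tracks import SignalTrack, mean_signal_many
from .methylome import TranscriptAnchor


@dataclass
class AnchoredMatrix:
    anchors: list[TranscriptAnchor]
    flank: int
    bin_size: int
    values: np.ndarray  # anchors x (2*flank/bin_size)

    def __post_init__(self) -> None:
        nb = 2 * self.flank // self.bin_size
        if 2 * self.flank % self.bin_size != 0:
            raise ValueError("2*flank must be a multiple of bin_size")
        if self.values.shape != (len(self.anchors), nb):
            raise ValueError(
                f"values shape {self.values.shape} != ({len(self.anchors)}, {nb})"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def subset(self, indices) -> "AnchoredMatrix":
        indices = np.asarray(indices)
        return AnchoredMatrix(
            [self.anchors[i] for i in indices],
            self.flank,
            self.bin_size,
            self.values[indices],
        )

    # -- I/O: gzip TSV with a one-line header --------------------------------

    def to_tsv(self, path) -> None:
        with gzip.open(path, "wt") as fh:
            fh.write(f"#flank={self.flank}\tbin={self.bin_size}\n")
            cols = "\t".join(f"b{i}" for i in range(self.n_bins))
            fh.write(f"gene_id\ttranscript_id\tchrom\ttss\tstrand\t{cols}\n")
            for a, row in zip(self.anchors, self.values):
                vals = "\t".join(f"{x:g}" for x in row)
                fh.write(
                    f"{a.gene_id}\t{a.transcript_id}\t{a.chrom}\t{a.tss}\t{a.strand}\t{vals}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "AnchoredMatrix":
        with gzip.open(path, "rt") as fh:
            header = fh.readline().strip().lstrip("#")
            meta = dict(kv.split("=") for kv in header.split("\t"))
            df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
        anchors = [
            TranscriptAnchor(r.gene_id, r.transcript_id, r.chrom, int(r.tss), r.strand)
            for r in df.itertuples()
        ]
        values = df[[c for c in df.columns if c.startswith("b")]].to_numpy(float)
        return cls(anchors, int(meta["flank"]), int(meta["bin"]), values)


@dataclass
class ProfileRatio:
    """Per-bin hypo/hyper ratio with its extremes.

    ``proximal_*`` restrict to bins within ``proximal_bp`` of the TSS, since
    ratio extremes over the whole 2-kb window and over the TSS-proximal
    sub-window can differ; both are reported.
    """

    ratio: np.ndarray
    min_ratio: float
    max_ratio: float
    proximal_bp: int
    proximal_min: float
    proximal_max: float
    proximal_mean: float


def anchored_matrix(
    track: SignalTrack,
    anchors: list[TranscriptAnchor],
    flank: int = 1000,
    bin_size: int = 10,
    chrom_sizes: dict[str, int] | None = None,
) -> AnchoredMatrix:
    """Mean track signal per 10-bp bin around each TSS (strand-oriented).

    Anchors whose window would extend past a chromosome edge are dropped
    with a warning rather than zero-padded.
    """
    nb = 2 * flank // bin_size
    kept = []
    for a in anchors:
        if a.tss - flank < 0:
            continue
        if chrom_sizes is not None and a.tss + flank > chrom_sizes.get(a.chrom, np.inf):
            continue
        kept.append(a)
    if len(kept) < len(anchors):
        warnings.warn(f"dropped {len(anchors) - len(kept)} clipped anchor windows")
    values = np.zeros((len(kept), nb))
    by_chrom: dict[str, list[int]] = {}
    for i, a in enumerate(kept):
        by_chrom.setdefault(a.chrom, []).append(i)
    offsets = np.arange(nb) * bin_size
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        win_starts = np.array([kept[i].tss - flank for i in idx], dtype=np.int64)
        bin_starts = (win_starts[:, None] + offsets[None, :]).ravel()
        means = mean_signal_many(track, chrom, bin_starts, bin_starts + bin_size)
        values[idx] = means.reshape(len(idx), nb)
    for i, a in enumerate(kept):
        if a.strand == "-":
            values[i] = values[i][::-1]
    return AnchoredMatrix(kept, flank, bin_size, values)


def pqs_density_matrix(
    pqs_list,
    anchors: list[TranscriptAnchor],
    flank: int = 1000,
    bin_size: int = 10,
    chrom_sizes: dict[str, int] | None = None,
) -> AnchoredMatrix:
    """PQS base coverage per bin (PQS bases overlapping the bin / bin width).

    Plus- and minus-strand PQSs are pooled; overlapping PQSs add.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in pqs_list:
        iv = p.interval
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    runs = {}
    for chrom, ivs in per_chrom.items():
        # breakpoint sweep: coverage counts how many PQSs span each segment
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        bps = np.unique(np.concatenate([starts, ends]))
        delta = np.zeros(len(bps), dtype=np.int64)
        np.add.at(delta, np.searchsorted(bps, starts), 1)
        np.add.at(delta, np.searchsorted(bps, ends), -1)
        cov = np.cumsum(delta)[:-1]
        keep = cov > 0
        runs[chrom] = (bps[:-1][keep], bps[1:][keep], cov[keep].astype(float))
    coverage = SignalTrack(runs)
    return anchored_matrix(coverage, anchors, flank, bin_size, chrom_sizes)


def methylation_matrix(
    calls,
    anchors: list[TranscriptAnchor],
    flank: int = 1000,
    bin_size: int = 10,
) -> AnchoredMatrix:
    """Per-bin window methylation level (percent) around each TSS.

    Bins with no covered CpG read as 0; rows of minus-strand anchors are
    flipped like every anchored matrix.  Used as the row-ordering key for
    heatmaps (sorted by decreasing methylation).
    """
    nb = 2 * flank // bin_size
    kept = [a for a in anchors if a.tss - flank >= 0]
    if len(kept) < len(anchors):
        warnings.warn(f"dropped {len(anchors) - len(kept)} clipped anchor windows")
    values = np.zeros((len(kept), nb))
    by_chrom: dict[str, list[int]] = {}
    for i, a in enumerate(kept):
        by_chrom.setdefault(a.chrom, []).append(i)
    offsets = np.arange(nb) * bin_size
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        win_starts = np.array([kept[i].tss - flank for i in idx], dtype=np.int64)
        bin_starts = (win_starts[:, None] + offsets[None, :]).ravel()
        _, mean = calls.window_stats(chrom, bin_starts, bin_starts + bin_size)
        values[idx] = np.nan_to_num(mean.reshape(len(idx), nb))
    for i, a in enumerate(kept):
        if a.strand == "-":
            values[i] = values[i][::-1]
    return AnchoredMatrix(kept, flank, bin_size, values)


def mean_profile(matrix: AnchoredMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise mean and SEM (sd/sqrt(n); 0 for a single row)."""
    n = matrix.values.shape[0]
    if n == 0:
        raise ValueError("cannot profile an empty matrix")
    mean = matrix.values.mean(axis=0)
    if n == 1:
        return mean, np.zeros_like(mean)
    sem = matrix.values.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, sem


def order_rows_by(matrix: AnchoredMatrix, key_matrix: AnchoredMatrix) -> AnchoredMatrix:
    """Reorder rows by decreasing row-mean of key_matrix (stable for ties).

    Used to sort signal heatmaps by decreasing methylation intensity.
    """
    if [a.transcript_id for a in matrix.anchors] != [
        a.transcript_id for a in key_matrix.anchors
    ]:
        raise ValueError("matrix and key_matrix must share the same anchors")
    order = np.argsort(-key_matrix.row_means(), kind="stable")
    return matrix.subset(order)


def profile_ratio(
    profile_hypo: np.ndarray,
    profile_hyper: np.ndarray,
    pseudocount: float = 1e-3,
    flank: int = 1000,
    bin_size: int = 10,
    proximal_bp: int = 200,
) -> ProfileRatio:
    """Per-bin (hypo + pc) / (hyper + pc) with whole-window and TSS-proximal extremes."""
    hypo = np.asarray(profile_hypo, dtype=float)
    hyper = np.asarray(profile_hyper, dtype=float)
    if hypo.shape != hyper.shape:
        raise ValueError("profiles must share the same bin grid")
    ratio = (hypo + pseudocount) / (hyper + pseudocount)
    nb = len(ratio)
    half = nb // 2
    k = proximal_bp // bin_size
    prox = ratio[max(half - k, 0) : min(half + k, nb)]
    return ProfileRatio(
        ratio=ratio,
        min_ratio=float(ratio.min()),
        max_ratio=float(ratio.max()),
        proximal_bp=proximal_bp,
        proximal_min=float(prox.min()),
        proximal_max=float(prox.max()),
        proximal_mean=float(prox.mean()),
    )


def write_profile_tsv(path, mean: np.ndarray, sem: np.ndarray, flank: int, bin_size: int) -> None:
    nb = len(mean)
    pos = -flank + bin_size * np.arange(nb) + bin_size // 2
    pd.DataFrame({"bin_center": pos, "mean": mean, "sem": sem}).to_csv(
        path, sep="\t", index=False
    )


def plot_profiles(profiles: dict[str, np.ndarray], flank: int, bin_size: int, path) -> None:
    """Optional line-plot output (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nb = len(next(iter(profiles.values())))
    x = -flank + bin_size * np.arange(nb) + bin_size / 2
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, prof in profiles.items():
        ax.plot(x, prof, label=label)
    ax.axvline(0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("signal")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
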