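"""End-to-end orchestration: simulate -> scan -> methylome -> profiles -> integrate.

A single declarative config file (YAML or JSON) drives one reproducible run;
all analysis defaults (1 kb flanks, 10-bp bins, top-N selection, 50%
methylation threshold, p < 0.05 and |log2FC| > 1) are named, overridable
keys.  Outputs are stage TSVs, a run log and a machine-readable
``report.json``; the report is deterministic for a given (config, seed)
(timestamps live only in the log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_tracks import (
    PeakSet,
    SignalTrack,
    bpm_normalize,
    mean_signal_many,
    overlaps,
    subtract_background,
    write_bed,
    write_bedgraph,
)
from .integrate import (
    build_pqs_joint_table,
    chrom_log2_ratio,
    de_filter,
    nondifferential_atac_peaks,
    pearson_g4_atac,
    promoter_g4_link,
    stratified_summary,
)
from .meta_signal import (
    anchored_matrix,
    mean_profile,
    methylation_matrix,
    order_rows_by,
    pqs_density_matrix,
    profile_ratio,
    write_profile_tsv,
)
from .methylome import select_hyper_hypo, write_selection_tsv
from .pqs_scan import annotate_cpg_all, scan_canonical_pqs, write_pqs_bed, write_pqs_tsv
from .synthetic_data import SimConfig, simulate_dataset, simulate_expression, write_dataset

logger = logging.getLogger("g4meth")

ANALYSIS_DEFAULTS = {
    "flank": 1000,
    "bin": 10,
    "top_n": 10000,
    "min_sites": 1,
    "meth_threshold_pct": 50.0,
    "pseudocount": 1e-3,
    "proximal_bp": 200,
    "p_max": 0.05,
    "lfc_min": 1.0,
    "m_cutoff": 1.0,
    "log2_pseudo": 1.0,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    simulation: SimConfig
    analysis: dict
    seed: int

    @classmethod
    def load(cls, path, seed: int | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "simulation" not in raw:
            raise ValueError(f"{path}: config must contain a 'simulation' section")
        sim = dict(raw["simulation"])
        cfg_seed = int(sim.pop("seed", 0))
        analysis = dict(ANALYSIS_DEFAULTS)
        extra = raw.get("analysis") or {}
        unknown = set(extra) - set(analysis)
        if unknown:
            raise ValueError(f"{path}: unknown analysis keys {sorted(unknown)}")
        analysis.update(extra)
        return cls(
            simulation=SimConfig.from_dict(sim),
            analysis=analysis,
            seed=seed if seed is not None else cfg_seed,
        )

    def digest(self) -> str:
        blob = json.dumps(
            {"simulation": self.simulation.__dict__, "analysis": self.analysis, "seed": self.seed},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def normalize_signal(track: SignalTrack, background: SignalTrack | None, bin_size: int) -> SignalTrack:
    """BPM-normalize a count track (and background) and subtract the background."""
    reads = max(int(round(track.total() / bin_size)), 1)
    norm = bpm_normalize(track, reads)
    if background is None:
        return norm
    bg_reads = max(int(round(background.total() / bin_size)), 1)
    return subtract_background(norm, bpm_normalize(background, bg_reads))


def peak_read_counts(track: SignalTrack, peaks: PeakSet, bin_size: int) -> np.ndarray:
    """Approximate per-peak read counts (track area / bin width)."""
    counts = np.zeros(len(peaks))
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(peaks):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        idx = np.asarray(idx)
        s = np.array([peaks[i].start for i in idx], dtype=np.int64)
        e = np.array([peaks[i].end for i in idx], dtype=np.int64)
        counts[idx] = mean_signal_many(track, chrom, s, e) * (e - s) / bin_size
    return counts


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kw):
            t0 = time.time()
            logger.info("stage %s ...", name)
            try:
                out = fn(*args, **kw)
            except Exception as err:
                raise PipelineError(f"stage '{name}' failed: {err}") from err
            logger.info("stage %s done (%.1fs)", name, time.time() - t0)
            return out

        return wrapped

    return deco


def run_all(config_path, out_dir, seed: int | None = None) -> dict:
    """Execute every stage in dependency order and write a summary report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    stream = logging.StreamHandler(sys.stderr)
    logger.setLevel(logging.INFO)
    logger.addHandler(handler)
    logger.addHandler(stream)
    failed_marker = out / "FAILED"
    try:
        cfg = RunConfig.load(config_path, seed)
        logger.info(
            "g4meth %s | seed %d | config %s (sha %s)",
            __version__, cfg.seed, config_path, cfg.digest(),
        )
        report = _run(cfg, out)
        report_path = out / "report.json"
        with open(report_path, "wt") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        logger.info("report written to %s", report_path)
        if failed_marker.exists():
            failed_marker.unlink()
        return report
    except Exception as err:
        failed_marker.write_text(f"{type(err).__name__}: {err}\n")
        logger.error("run failed: %s", err)
        raise
    finally:
        logger.removeHandler(handler)
        logger.removeHandler(stream)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> dict:
    an = cfg.analysis
    flank, bin_size = int(an["flank"]), int(an["bin"])

    simulate = _stage("simulate")(lambda c, s: simulate_dataset(c, s))
    ds_wt = simulate(cfg.simulation.replace(condition="WT"), cfg.seed)
    ds_ko = simulate(cfg.simulation.replace(condition="KO"), cfg.seed)
    write_dataset(ds_wt, out / "sim")
    write_dataset(ds_ko, out / "sim")

    @_stage("scan")
    def scan():
        pqs = []
        for chrom in sorted(ds_wt.genome):
            pqs.extend(scan_canonical_pqs(ds_wt.genome[chrom], chrom))
        return annotate_cpg_all(pqs, ds_wt.genome)

    pqs = scan()
    write_pqs_bed(pqs, out / "pqs.bed")
    write_pqs_tsv(pqs, out / "pqs.tsv")

    @_stage("methylome")
    def meth_select():
        return select_hyper_hypo(
            ds_wt.anchors, ds_wt.calls, flank=flank,
            top_n=int(an["top_n"]), min_sites=int(an["min_sites"]),
        )

    selection = meth_select()
    write_selection_tsv(selection, out / "methyl_selection.tsv")

    @_stage("normalize")
    def normalize():
        g4_wt = normalize_signal(ds_wt.g4_track, ds_wt.igg_track, bin_size)
        g4_ko = normalize_signal(ds_ko.g4_track, ds_ko.igg_track, bin_size)
        atac_wt = normalize_signal(ds_wt.atac_track, None, bin_size)
        atac_ko = normalize_signal(ds_ko.atac_track, None, bin_size)
        return g4_wt, g4_ko, atac_wt, atac_ko

    g4_wt, g4_ko, atac_wt, atac_ko = normalize()
    write_bedgraph(g4_wt, out / "g4_wt_norm.bedgraph")
    write_bedgraph(g4_ko, out / "g4_ko_norm.bedgraph")

    @_stage("profiles")
    def profiles():
        sizes = ds_wt.chrom_sizes
        out_d = {}
        for label, anchors in (("hyper", selection.hyper), ("hypo", selection.hypo)):
            mat_g4 = anchored_matrix(g4_wt, anchors, flank, bin_size, sizes)
            mat_pqs = pqs_density_matrix(pqs, anchors, flank, bin_size, sizes)
            key = methylation_matrix(ds_wt.calls, anchors, flank, bin_size)
            mat_g4_sorted = order_rows_by(mat_g4, key)
            mat_g4_sorted.to_tsv(out / f"g4_matrix_{label}.tsv.gz")
            g4_mean, g4_sem = mean_profile(mat_g4)
            pqs_mean, pqs_sem = mean_profile(mat_pqs)
            write_profile_tsv(out / f"g4_profile_{label}.tsv", g4_mean, g4_sem, flank, bin_size)
            write_profile_tsv(out / f"pqs_profile_{label}.tsv", pqs_mean, pqs_sem, flank, bin_size)
            out_d[label] = {"g4": g4_mean, "pqs": pqs_mean}
        ratios = {
            kind: profile_ratio(
                out_d["hypo"][kind], out_d["hyper"][kind],
                pseudocount=float(an["pseudocount"]),
                flank=flank, bin_size=bin_size, proximal_bp=int(an["proximal_bp"]),
            )
            for kind in ("g4", "pqs")
        }
        return ratios

    ratios = profiles()

    @_stage("integrate")
    def integrate_stage():
        table = build_pqs_joint_table(
            pqs, ds_wt.g4_peaks, g4_wt, ds_wt.atac_peaks, atac_wt, ds_wt.calls,
            meth_threshold_pct=float(an["meth_threshold_pct"]),
        )
        table.to_csv(out / "pqs_joint_table.tsv", sep="\t", index=False)
        r = pearson_g4_atac(table)
        strata = stratified_summary(table)
        strata.summary.to_csv(out / "strata_summary.tsv", sep="\t")
        log2r = chrom_log2_ratio(g4_ko, g4_wt, pseudo=float(an["log2_pseudo"]))
        common_idx = np.flatnonzero(overlaps(ds_wt.atac_peaks, ds_ko.atac_peaks))
        common = PeakSet([ds_wt.atac_peaks[i] for i in common_idx])
        ca = peak_read_counts(ds_wt.atac_track, common, bin_size)
        cb = peak_read_counts(ds_ko.atac_track, common, bin_size)
        nondiff = nondifferential_atac_peaks(common, ca, cb, m_cutoff=float(an["m_cutoff"]))
        write_bed(nondiff, out / "atac_nondifferential.bed")
        return table, r, strata, log2r, len(common), nondiff

    table, pearson_r, strata, log2r, n_common, nondiff = integrate_stage()

    @_stage("expression")
    def expression():
        counts, de = simulate_expression(ds_wt.truth, ds_ko.truth, cfg.simulation, cfg.seed)
        counts.to_csv(out / "expression_counts.tsv", sep="\t", index=False)
        de.to_csv(out / "de_table.tsv", sep="\t", index=False)
        up, down = de_filter(de, p_max=float(an["p_max"]), lfc_min=float(an["lfc_min"]))
        sizes = ds_wt.chrom_sizes
        mat_wt = anchored_matrix(g4_wt, ds_wt.anchors, flank, bin_size, sizes)
        mat_ko = anchored_matrix(g4_ko, ds_wt.anchors, flank, bin_size, sizes)
        link = promoter_g4_link(up, ds_wt.anchors, mat_wt, mat_ko)
        link.per_gene.to_csv(out / "promoter_g4_link.tsv", sep="\t", index=False)
        return up, down, link

    up, down, link = expression()

    report = {
        "version": __version__,
        "seed": cfg.seed,
        "config_sha": cfg.digest(),
        "pqs": {
            "n_total": len(pqs),
            "n_plus": sum(1 for p in pqs if p.interval.strand == "+"),
            "n_minus": sum(1 for p in pqs if p.interval.strand == "-"),
        },
        "methylation": {
            "n_hyper": len(selection.hyper),
            "n_hypo": len(selection.hypo),
        },
        "profile_ratio": {
            kind: {
                "min": ratios[kind].min_ratio,
                "max": ratios[kind].max_ratio,
                "proximal_min": ratios[kind].proximal_min,
                "proximal_max": ratios[kind].proximal_max,
                "proximal_mean": ratios[kind].proximal_mean,
            }
            for kind in ratios
        },
        "joint_table": {"n_pqs": int(len(table))},
        "pearson_g4_atac": pearson_r,
        "strata": {
            "means": {s: _nan_none(strata.summary.loc[s, "mean"]) for s in strata.summary.index},
            "n": {s: int(strata.summary.loc[s, "n"]) for s in strata.summary.index},
            "tests": {k: (list(v) if v else None) for k, v in strata.tests.items()},
        },
        "chrom_log2_ratio": log2r,
        "nondifferential_atac": {"n_common": n_common, "n_retained": len(nondiff)},
        "de": {"n_up": len(up), "n_down": len(down)},
        "promoter_g4_link": {
            "n_resolved": link.n_resolved,
            "n_dropped": link.n_dropped,
            "mean_delta": link.mean_delta,
            "paired_p": _nan_none(link.paired_p),
        },
    }
    return report


def _nan_none(x):
    x = float(x)
    return None if np.isnan(x) else x
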