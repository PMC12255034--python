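"""Calibrated recovery of the G4-ATAC coupling correlation.

The packaged fixture configuration stores the target Pearson correlation
between per-PQS G4 and ATAC signal together with the simulation geometries
used to recover it.  The workflow: calibrate the accessibility coupling
beta_a on small cohorts until the simulated correlation matches the target,
then simulate one large independent cohort with the calibrated coupling and
re-measure the correlation through the full pipeline (scan -> joint table ->
Pearson).
"""

from __future__ import annotations

import importlib.resources
import json

from .integrate import build_pqs_joint_table, pearson_g4_atac
from .pqs_scan import annotate_cpg_all, scan_canonical_pqs
from .synthetic_data import SimConfig, calibrate_coupling, simulate_dataset


def load_fixture_config() -> dict:
    """The packaged fixture: target correlation and simulation geometries."""
    path = importlib.resources.files("g4meth.data") / "fixture_config.json"
    return json.loads(path.read_text())


def calibrated_pearson_recovery(seed: int) -> dict:
    """Calibrate beta_a to the fixture target, then re-measure on a cohort.

    Calibration averages over five seeds derived from ``seed``; the cohort
    uses an independent seed.  Returns the calibrated coupling, the
    calibration-time correlation, and the cohort correlation with its size.
    """
    fx = load_fixture_config()
    target = float(fx["target_pearson_r"])
    cal_cfg = SimConfig.from_dict(fx["calibration"])
    beta_a, achieved = calibrate_coupling(
        target,
        cal_cfg,
        seeds=[seed + k for k in range(1, 6)],
        beta_lo=float(fx["beta_lo"]),
        beta_hi=float(fx["beta_hi"]),
        tol=float(fx["tol"]),
    )
    cohort_cfg = SimConfig.from_dict(fx["cohort"]).replace(beta_a=beta_a)
    ds = simulate_dataset(cohort_cfg, seed + 11)
    pqs = []
    for chrom in sorted(ds.genome):
        pqs.extend(scan_canonical_pqs(ds.genome[chrom], chrom))
    pqs = annotate_cpg_all(pqs, ds.genome)
    table = build_pqs_joint_table(
        pqs, ds.g4_peaks, ds.g4_track, ds.atac_peaks, ds.atac_track, ds.calls
    )
    r = pearson_g4_atac(table)
    return {
        "target_r": target,
        "beta_a": float(beta_a),
        "calibration_r": float(achieved),
        "cohort_r": float(r),
        "n_pqs": int(len(table)),
    }
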