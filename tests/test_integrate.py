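"""Joint PQS table, stratification, coupling and DE linkage."""

import numpy as np
import pandas as pd
import pytest

from g4meth.core_tracks import GenomeInterval, PeakSet, SignalTrack
from g4meth.integrate import (
    build_pqs_joint_table,
    chrom_log2_ratio,
    de_filter,
    nondifferential_atac_peaks,
    pearson_g4_atac,
    promoter_fraction,
    promoter_g4_link,
    stratified_summary,
)
from g4meth.meta_signal import AnchoredMatrix
from g4meth.methylome import CpGCall, MethylCalls, TranscriptAnchor
from g4meth.pqs_scan import PQSRecord


def uniform_track(value, length=10_000, chrom="c"):
    return SignalTrack({chrom: (np.array([0]), np.array([length]), np.array([float(value)]))})


def pqs_at(start, cpgs=(), chrom="c", strand="+"):
    end = start + 20
    return PQSRecord(
        GenomeInterval(chrom, start, end, strand), "G" * 20, (0, 5, 10, 15), (2, 2, 2),
        tuple(cpgs),
    )


class TestJointTable:
    def fixture(self):
        """6 hand-annotated PQSs: 2x2 strata + no-CpG + no-peak cases."""
        pqs = [
            pqs_at(100, (105,)),   # open, high meth, G4 peak
            pqs_at(300, (305,)),   # open, low meth, G4 peak
            pqs_at(2100, (2105,)), # closed, high meth, G4 peak
            pqs_at(2300, (2305,)), # closed, low meth, G4 peak
            pqs_at(2500),          # no CpG -> excluded by filter
            pqs_at(2700, (2705,)), # no G4 peak -> excluded by filter
        ]
        g4_peaks = PeakSet([GenomeInterval("c", 0, 2600)])
        atac_peaks = PeakSet([GenomeInterval("c", 0, 1000)])
        calls = MethylCalls.from_calls(
            [
                CpGCall("c", 105, "+", 8, 10),
                CpGCall("c", 305, "+", 1, 10),
                CpGCall("c", 2105, "+", 9, 10),
                CpGCall("c", 2305, "+", 2, 10),
                CpGCall("c", 2705, "+", 9, 10),
            ]
        )
        return pqs, g4_peaks, atac_peaks, calls

    def test_fixture_flags_match_hand_annotation(self):
        pqs, g4_peaks, atac_peaks, calls = self.fixture()
        table = build_pqs_joint_table(
            pqs, g4_peaks, uniform_track(2.0), atac_peaks, uniform_track(1.0), calls,
            require_g4_and_cpg=False,
        )
        assert len(table) == 6
        by_start = table.set_index("start")
        assert bool(by_start.loc[100, "open"]) and by_start.loc[100, "meth_state"] == "high"
        assert bool(by_start.loc[300, "open"]) and by_start.loc[300, "meth_state"] == "low"
        assert not by_start.loc[2100, "open"]
        assert by_start.loc[2100, "meth_state"] == "high"
        assert by_start.loc[2500, "meth_state"] == "undefined"
        assert not by_start.loc[2700, "has_g4_peak"]

    def test_filter_keeps_g4_peak_with_cpg(self):
        pqs, g4_peaks, atac_peaks, calls = self.fixture()
        table = build_pqs_joint_table(
            pqs, g4_peaks, uniform_track(2.0), atac_peaks, uniform_track(1.0), calls
        )
        assert sorted(table.start) == [100, 300, 2100, 2300]

    def test_row_order_deterministic(self):
        pqs, g4_peaks, atac_peaks, calls = self.fixture()
        table = build_pqs_joint_table(
            pqs[::-1], g4_peaks, uniform_track(2.0), atac_peaks, uniform_track(1.0),
            calls, require_g4_and_cpg=False,
        )
        assert list(table.start) == sorted(table.start)

    def test_stratum_additivity(self):
        pqs, g4_peaks, atac_peaks, calls = self.fixture()
        table = build_pqs_joint_table(
            pqs, g4_peaks, uniform_track(2.0), atac_peaks, uniform_track(1.0), calls,
            require_g4_and_cpg=False,
        )
        s = stratified_summary(table).summary
        assert s.loc["open", "n"] + s.loc["closed", "n"] == s.loc["all", "n"]
        n_open_undef = (
            (table["open"] & (table.meth_state == "undefined")).sum()
        )
        assert (
            s.loc["open_hypo", "n"] + s.loc["open_hyper", "n"] + n_open_undef
            == s.loc["open", "n"]
        )


class TestPearson:
    def _table(self, atac, g4):
        return pd.DataFrame({"atac_signal": atac, "g4_signal": g4})

    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson_g4_atac(self._table(x, 2 * x)) == pytest.approx(1.0)
        assert pearson_g4_atac(self._table(x, -x + 11)) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.random(20), rng.random(20)
        r = pearson_g4_atac(self._table(x, y))
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected)

    def test_affine_invariance(self, rng):
        x, y = rng.random(30), rng.random(30)
        r1 = pearson_g4_atac(self._table(x, y))
        r2 = pearson_g4_atac(self._table(3.5 * x + 2, 0.1 * y + 7))
        assert r1 == pytest.approx(r2)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            pearson_g4_atac(self._table([1, 2], [3, 4]))
        with pytest.raises(ValueError):
            pearson_g4_atac(self._table([1.0, 1.0, 1.0], [1, 2, 3]))


class TestStratifiedSummary:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["g4_signal", "open", "meth_state"])

    def test_hand_fixture_means(self):
        rows = (
            [(10.0, True, "low")] * 3
            + [(4.0, True, "high")] * 3
            + [(6.0, False, "low")] * 3
            + [(2.0, False, "high")] * 3
        )
        s = stratified_summary(self._table(rows))
        assert s.summary.loc["open_hypo", "mean"] == pytest.approx(10.0)
        assert s.summary.loc["closed_hyper", "mean"] == pytest.approx(2.0)
        assert s.summary.loc["open", "mean"] == pytest.approx(7.0)
        assert s.summary.loc["hypo", "mean"] == pytest.approx(8.0)

    def test_identical_signal_not_significant(self):
        rows = [(5.0, o, m) for o in (True, False) for m in ("low", "high")] * 3
        s = stratified_summary(self._table(rows))
        for res in s.tests.values():
            # identical values give t=0 (p=1) or an undefined statistic (nan)
            assert res is None or res[1] == pytest.approx(1.0) or np.isnan(res[1])

    def test_empty_stratum_marked_unavailable(self):
        rows = [(5.0, True, "low")] * 4
        s = stratified_summary(self._table(rows))
        assert s.tests["open_vs_closed"] is None
        assert s.summary.loc["closed", "n"] == 0


class TestNondifferentialAtacPeaks:
    def _peaks(self, n):
        return PeakSet([GenomeInterval("c", 100 * i, 100 * i + 50) for i in range(n)])

    def test_identical_counts_all_retained(self):
        counts = np.array([10.0, 40.0, 90.0])
        out = nondifferential_atac_peaks(self._peaks(3), counts, counts, 1.0)
        assert len(out) == 3
        assert all(iv.score == pytest.approx(0.0) for iv in out)

    def test_fourfold_peak_excluded(self):
        a = np.array([10.0, 20.0, 30.0, 160.0])
        b = np.array([10.0, 20.0, 30.0, 40.0])
        out = nondifferential_atac_peaks(self._peaks(4), a, b, 1.0)
        assert [iv.start for iv in out] == [0, 100, 200]

    def test_global_depth_shift_absorbed_by_median(self):
        b = np.array([10.0, 20.0, 40.0, 80.0, 160.0])
        out = nondifferential_atac_peaks(self._peaks(5), 2 * b, b, 1.0)
        assert len(out) == 5
        # rescaled M values match a direct computation
        m = np.log2((2 * b + 1) / (b + 1))
        expected = m - np.median(m)
        np.testing.assert_allclose([iv.score for iv in out], expected, atol=1e-12)

    def test_empty_input_empty_output(self):
        assert len(nondifferential_atac_peaks(PeakSet(), np.array([]), np.array([]))) == 0


class TestChromLog2Ratio:
    def test_identical_tracks_zero(self, step_track):
        out = chrom_log2_ratio(step_track, step_track)
        assert all(v == pytest.approx(0.0) for v in out.values())

    def test_doubled_track_is_one(self, step_track):
        doubled = step_track.map_values(lambda v: 2 * v)
        out = chrom_log2_ratio(doubled, step_track, pseudo=1e-9)
        for v in out.values():
            assert v == pytest.approx(1.0, abs=1e-6)

    def test_matches_summation_oracle(self, rng):
        from conftest import random_track

        ko, wt = random_track(rng), random_track(rng)
        out = chrom_log2_ratio(ko, wt, pseudo=0.5)
        s, e, v = ko.runs("chr1")
        total_ko = float(np.sum(v * (e - s)))
        s, e, v = wt.runs("chr1")
        total_wt = float(np.sum(v * (e - s)))
        assert out["chr1"] == pytest.approx(np.log2((total_ko + 0.5) / (total_wt + 0.5)))

    def test_chrom_missing_in_one_track(self, step_track):
        only_chr1 = SignalTrack(
            {"chr1": (np.array([0]), np.array([10]), np.array([1.0]))}
        )
        out = chrom_log2_ratio(step_track, only_chr1)
        assert "chr2" in out  # present in one track -> reported


class TestDeFilter:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p_value"])

    def test_strict_boundaries_enumerated(self):
        table = self._table(
            [
                ("boundary_fc", 1.0, 0.01),    # |log2FC| not > 1 -> neither
                ("clear_up", 2.0, 0.01),
                ("clear_down", -3.0, 0.001),
                ("boundary_p", 1.5, 0.05),     # p not < 0.05 -> neither
                ("weak", 0.5, 0.001),
                ("insignificant", 4.0, 0.2),
            ]
        )
        up, down = de_filter(table)
        assert up == ["clear_up"]
        assert down == ["clear_down"]

    def test_counts_match_enumeration(self, rng):
        n = 200
        table = self._table(
            list(zip([f"g{i}" for i in range(n)],
                     rng.normal(0, 2, n), rng.random(n)))
        )
        up, down = de_filter(table, p_max=0.1, lfc_min=0.5)
        expected_up = ((table.p_value < 0.1) & (table.log2fc > 0.5)).sum()
        expected_down = ((table.p_value < 0.1) & (table.log2fc < -0.5)).sum()
        assert (len(up), len(down)) == (expected_up, expected_down)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            de_filter(self._table([("g", 1.0, 1.5)]))


class TestPromoterG4Link:
    def _matrices(self, n, delta=0.0, rng=None):
        anchors = [TranscriptAnchor(f"g{i}", f"g{i}.t", "c", 2000 + 4000 * i, "+") for i in range(n)]
        base = rng.random((n, 200)) if rng is not None else np.ones((n, 200))
        wt = AnchoredMatrix(anchors, 1000, 10, base)
        ko = AnchoredMatrix(anchors, 1000, 10, base + delta)
        return anchors, wt, ko

    def test_equal_matrices_zero_delta(self):
        anchors, wt, ko = self._matrices(5)
        link = promoter_g4_link([a.gene_id for a in anchors], anchors, wt, ko)
        assert link.mean_delta == pytest.approx(0.0)

    def test_uniform_shift_recovered(self, rng):
        anchors, wt, ko = self._matrices(6, delta=1.0, rng=rng)
        link = promoter_g4_link([a.gene_id for a in anchors], anchors, wt, ko)
        assert link.mean_delta == pytest.approx(1.0)
        np.testing.assert_allclose(link.per_gene.delta, 1.0)

    def test_unresolvable_genes_counted(self, rng):
        anchors, wt, ko = self._matrices(4, delta=0.5, rng=rng)
        genes = [a.gene_id for a in anchors[:2]] + ["missing1", "missing2"]
        link = promoter_g4_link(genes, anchors, wt, ko)
        assert link.n_resolved == 2 and link.n_dropped == 2

    def test_row_mean_oracle(self, rng):
        anchors, wt, ko = self._matrices(3, delta=0.25, rng=rng)
        link = promoter_g4_link(["g1"], anchors, wt, ko)
        assert link.per_gene.loc[0, "mean_wt"] == pytest.approx(wt.values[1].mean())

    def test_all_unresolvable_errors(self, rng):
        anchors, wt, ko = self._matrices(2, rng=rng)
        with pytest.raises(ValueError):
            promoter_g4_link(["nope"], anchors, wt, ko)


class TestPromoterFraction:
    def test_share_of_peaks_in_promoters(self):
        anchors = [TranscriptAnchor("g", "t", "c", 5000, "+")]
        peaks = PeakSet(
            [GenomeInterval("c", 4500, 4600), GenomeInterval("c", 9000, 9100)]
        )
        assert promoter_fraction(peaks, anchors) == pytest.approx(0.5)
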