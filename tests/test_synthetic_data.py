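"""Generator determinism, planted-motif recovery and coupling behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4meth.methylome import window_methylation_level
from g4meth.core_tracks import GenomeInterval
from g4meth.pqs_scan import scan_canonical_pqs
from g4meth.synthetic_data import (
    SimConfig,
    bisulfite_convert,
    formation_probability,
    gene_occupancy,
    generate_genome,
    simulate_atac,
    simulate_dataset,
    simulate_expression,
    simulate_g4,
    simulate_methylome,
)

SMALL = SimConfig(n_genes=40, n_chroms=2, n_pqs_per_promoter=1)


class TestGenerateGenome:
    def test_scanner_recovers_planted_coordinates(self):
        cfg = SimConfig(n_genes=10, n_chroms=1, n_pqs_per_promoter=1)
        genome, anchors, truth = generate_genome(cfg, 3)
        found = set()
        for chrom, seq in genome.items():
            for r in scan_canonical_pqs(seq, chrom):
                found.add((r.interval.chrom, r.interval.start, r.interval.end, r.interval.strand))
        planted = set(
            map(tuple, truth.pqs[["chrom", "start", "end", "strand"]].itertuples(index=False))
        )
        assert planted <= found
        assert len(planted) == 10

    def test_same_seed_identical_fasta(self):
        g1, a1, t1 = generate_genome(SMALL, 5)
        g2, a2, t2 = generate_genome(SMALL, 5)
        assert g1 == g2 and a1 == a2
        assert t1.pqs.equals(t2.pqs)

    def test_different_seed_differs(self):
        g1, _, _ = generate_genome(SMALL, 5)
        g2, _, _ = generate_genome(SMALL, 6)
        assert g1 != g2

    def test_zero_pqs_config_plants_nothing(self):
        cfg = SimConfig(n_genes=10, n_chroms=1, n_pqs_per_promoter=0)
        genome, _, truth = generate_genome(cfg, 1)
        assert len(truth.pqs) == 0
        # chance PQSs may still occur in the random background; report only
        n_chance = sum(len(scan_canonical_pqs(s, c)) for c, s in genome.items())
        assert n_chance >= 0

    def test_every_planted_pqs_contains_a_cpg(self):
        genome, _, truth = generate_genome(SMALL, 9)
        for row in truth.pqs.itertuples():
            assert "CG" in genome[row.chrom][row.start : row.end]

    def test_overcrowded_config_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(SimConfig(n_genes=4, n_chroms=1, n_pqs_per_promoter=30), 1)


class TestSimulateMethylome:
    def test_deterministic_and_condition_scaling(self):
        genome, _, truth_wt = generate_genome(SMALL, 2)
        _, _, truth_ko = generate_genome(SMALL, 2)
        calls_wt = simulate_methylome(genome, truth_wt, SMALL, 2)
        calls_ko = simulate_methylome(
            genome, truth_ko, SMALL.replace(condition="KO", ko_meth_scale=0.5), 2
        )
        # same CpG sites, true levels exactly halved
        for chrom in truth_wt.cpg_positions:
            np.testing.assert_array_equal(
                truth_wt.cpg_positions[chrom], truth_ko.cpg_positions[chrom]
            )
            np.testing.assert_allclose(
                truth_ko.cpg_true_level[chrom], 0.5 * truth_wt.cpg_true_level[chrom]
            )
        # ko_meth_scale=1 reproduces WT exactly (same rng path)
        _, _, truth_same = generate_genome(SMALL, 2)
        calls_same = simulate_methylome(
            genome, truth_same, SMALL.replace(condition="WT"), 2
        )
        assert calls_same.df.equals(calls_wt.df)

    def test_site_levels_match_binomial_expectation(self):
        # deep coverage at a fixed true level: observed mean within 1% of truth
        cfg = SimConfig(
            n_genes=60, n_chroms=2, n_pqs_per_promoter=1,
            hyper_level=0.8, hypo_level=0.8, level_concentration=1e6,
            coverage_mean=30.0,
        )
        genome, _, truth = generate_genome(cfg, 4)
        calls = simulate_methylome(genome, truth, cfg, 4)
        df = calls.df[calls.df.n_total > 0]
        assert len(df) > 2000
        observed = 100.0 * df.n_meth.sum() / df.n_total.sum()
        assert observed == pytest.approx(80.0, abs=1.0)

    def test_low_coverage_leaves_windows_undefined(self):
        cfg = SMALL.replace(coverage_mean=0.001)
        genome, anchors, truth = generate_genome(cfg, 8)
        calls = simulate_methylome(genome, truth, cfg, 8)
        n_cpgs = sum(len(p) for p in truth.cpg_positions.values())
        assert len(calls.df) < 0.05 * n_cpgs  # most sites uncovered
        undefined = sum(
            window_methylation_level(calls, a.window(1000)) is None for a in anchors
        )
        assert undefined > len(anchors) / 2


class TestSimulateAtacAndG4:
    def test_same_seed_identical_tracks(self):
        genome, _, t1 = generate_genome(SMALL, 3)
        simulate_methylome(genome, t1, SMALL, 3)
        a1, p1 = simulate_atac(t1, SMALL, 3)
        genome, _, t2 = generate_genome(SMALL, 3)
        simulate_methylome(genome, t2, SMALL, 3)
        a2, p2 = simulate_atac(t2, SMALL, 3)
        assert a1 == a2 and p1 == p2

    def test_closed_only_config_has_no_peaks(self):
        genome, _, truth = generate_genome(SMALL, 3)
        simulate_methylome(genome, truth, SMALL, 3)
        _, peaks = simulate_atac(truth, SMALL.replace(open_fraction=0.0), 3)
        assert len(peaks) == 0

    def test_open_plateau_height_reflects_accessibility(self):
        cfg = SMALL.replace(open_fraction=1.0, atac_background=0.0)
        genome, anchors, truth = generate_genome(cfg, 6)
        simulate_methylome(genome, truth, cfg, 6)
        track, peaks = simulate_atac(truth, cfg, 6)
        from g4meth.core_tracks import mean_signal

        for row in truth.genes.itertuples():
            got = mean_signal(
                track, GenomeInterval(row.chrom, row.tss - 500, row.tss + 500)
            )
            expected = cfg.atac_amplitude * row.accessibility
            # Poisson noise averaged over 100 bins: allow a few sd
            assert got == pytest.approx(expected, abs=4 * np.sqrt(expected / 100) + 0.5)

    @pytest.mark.parametrize(
        "beta0,expect_all,expect_none",
        [(10.0, True, False), (-10.0, False, True)],
    )
    def test_logistic_saturation(self, beta0, expect_all, expect_none):
        cfg = SMALL.replace(beta0=beta0, beta_m=0.0, beta_a=0.0)
        genome, _, truth = generate_genome(cfg, 5)
        simulate_methylome(genome, truth, cfg, 5)
        simulate_atac(truth, cfg, 5)
        simulate_g4(truth, cfg, 5)
        if expect_all:
            assert truth.pqs.formed.all()
        if expect_none:
            assert not truth.pqs.formed.any()

    def test_formation_probability_closed_form(self):
        cfg = SimConfig(beta0=-2.0, beta_m=3.0, beta_a=0.0)
        p_unmeth = formation_probability(0.0, 0.3, cfg)
        p_meth = formation_probability(1.0, 0.3, cfg)
        assert p_unmeth == pytest.approx(1 / (1 + np.exp(-1.0)))
        assert p_meth == pytest.approx(1 / (1 + np.exp(2.0)))

    def test_methylation_inhibition_widens_hypo_hyper_gap(self):
        """Raising beta_m suppresses hypermethylated PQSs relative to hypo.

        In the logistic model the inhibition term acts through (1 - m), so
        increasing beta_m widens the hypo - hyper formation gap.
        """
        gaps = []
        for beta_m in (1.0, 3.0, 6.0):
            gap = []
            for seed in (1, 2, 3):
                cfg = SimConfig(
                    n_genes=600, n_chroms=2, n_pqs_per_promoter=3, beta_m=beta_m
                )
                genome, _, truth = generate_genome(cfg, seed)
                simulate_methylome(genome, truth, cfg, seed)
                simulate_atac(truth, cfg, seed)
                simulate_g4(truth, cfg, seed)
                hyper_idx = truth.genes.hyper.to_numpy()[truth.pqs.gene_idx]
                f_hyper = truth.pqs.formed.to_numpy()[hyper_idx].mean()
                f_hypo = truth.pqs.formed.to_numpy()[~hyper_idx].mean()
                gap.append(f_hypo - f_hyper)
            gaps.append(np.mean(gap))
        assert gaps[0] < gaps[1] < gaps[2]


class TestSimulateExpression:
    def _paired(self, cfg, seed):
        genome, _, twt = generate_genome(cfg, seed)
        simulate_methylome(genome, twt, cfg, seed)
        simulate_atac(twt, cfg, seed)
        simulate_g4(twt, cfg, seed)
        cko = cfg.replace(condition="KO")
        genome, _, tko = generate_genome(cko, seed)
        simulate_methylome(genome, tko, cko, seed)
        simulate_atac(tko, cko, seed)
        simulate_g4(tko, cko, seed)
        return twt, tko

    def test_zero_effect_zero_expected_lfc(self):
        cfg = SMALL.replace(expr_effect=0.0)
        twt, tko = self._paired(cfg, 11)
        _, de = simulate_expression(twt, tko, cfg, 11)
        np.testing.assert_allclose(de.expected_log2fc, 0.0)

    def test_unit_occupancy_contrast_doubles_expression(self):
        cfg = SMALL.replace(expr_effect=1.0)
        twt, tko = self._paired(cfg, 12)
        n = len(twt.genes)
        _, de = simulate_expression(
            twt, tko, cfg, 12, occ_wt=np.zeros(n), occ_ko=np.ones(n)
        )
        np.testing.assert_allclose(de.expected_log2fc, 1.0)

    def test_power_on_strong_true_effects(self):
        # genes with true |log2FC| >= 2 are mostly recovered by the DE filter
        from g4meth.integrate import de_filter

        cfg = SimConfig(n_genes=200, n_chroms=2, n_pqs_per_promoter=1, expr_effect=10.0)
        twt, tko = self._paired(cfg, 13)
        rng = np.random.default_rng(99)
        occ_wt = rng.uniform(0.0, 0.1, 200)
        occ_ko = rng.uniform(0.0, 1.0, 200)
        counts, de = simulate_expression(twt, tko, cfg, 13, occ_wt=occ_wt, occ_ko=occ_ko)
        up, down = de_filter(de)
        strong = de[de.expected_log2fc.abs() >= 2.0]
        assert len(strong) >= 20
        recovered = strong.gene_id.isin(up + down).mean()
        assert recovered > 0.8


class TestBisulfiteConvert:
    @pytest.mark.parametrize(
        "seq,meth,expected",
        [("ACGA", set(), "ATGA"), ("ACGA", {1}, "ACGA"), ("TTTT", set(), "TTTT")],
    )
    def test_examples(self, seq, meth, expected):
        assert bisulfite_convert(seq, meth) == expected

    def test_position_must_be_cytosine(self):
        with pytest.raises(ValueError):
            bisulfite_convert("ACGA", {0})

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_per_character_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
        c_pos = [i for i, ch in enumerate(seq) if ch == "C"]
        meth = {p for p in c_pos if rng.random() < 0.5}
        out = bisulfite_convert(seq, meth)
        for i, (a, b) in enumerate(zip(seq, out)):
            if a == "C" and i not in meth:
                assert b == "T"
            else:
                assert b == a


class TestDatasetDeterminism:
    def test_full_dataset_pure_function_of_config_and_seed(self):
        d1 = simulate_dataset(SMALL, 21)
        d2 = simulate_dataset(SMALL, 21)
        assert d1.genome == d2.genome
        assert d1.calls.df.equals(d2.calls.df)
        assert d1.g4_track == d2.g4_track
        assert d1.atac_track == d2.atac_track
        assert d1.truth.pqs.equals(d2.truth.pqs)

    def test_gene_occupancy_aggregates_pqs_probabilities(self):
        ds = simulate_dataset(SMALL, 22)
        occ = gene_occupancy(ds.truth)
        grouped = ds.truth.pqs.groupby("gene_idx").p_form.mean()
        np.testing.assert_allclose(occ[grouped.index.to_numpy()], grouped.to_numpy())
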