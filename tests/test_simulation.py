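from dataclasses import replace

import numpy as np
import pytest

from dkaryo.genomes import GRCH37_SIZES, is_autosome
from dkaryo.simulate import (
    SimConfig,
    TruthEvent,
    copy_ratio,
    expected_profile,
    read_truth_tsv,
    simulate_panel,
    simulate_sample,
    table1_fixture,
    write_truth_tsv,
)
from tests.conftest import SMALL_SIZES


class TestCopyRatio:
    def test_heterozygous_deletion_halves_fully_covered_bins(self, small_binset):
        ev = TruthEvent("1", 1_000_000, 2_000_000, "del")
        ratio = copy_ratio([ev], small_binset, "female")
        inside = [
            r for r, b in zip(ratio, small_binset.bins)
            if b.chrom == "1" and b.start >= 1_000_000 and b.end <= 2_000_000
        ]
        assert inside and all(r == pytest.approx(0.5) for r in inside)

    def test_half_clonality_duplication_gives_ratio_one_and_a_quarter(self, small_binset):
        ev = TruthEvent("1", 1_000_000, 2_000_000, "dup", fraction=0.5)
        ratio = copy_ratio([ev], small_binset, "female")
        inside = [
            r for r, b in zip(ratio, small_binset.bins)
            if b.chrom == "1" and b.start >= 1_000_000 and b.end <= 2_000_000
        ]
        assert all(r == pytest.approx(1.25) for r in inside)

    def test_partial_bin_overlap_scales_linearly(self, small_binset):
        ev = TruthEvent("1", 1_050_000, 2_000_000, "del")  # covers half of bin 10
        ratio = copy_ratio([ev], small_binset, "female")
        b10 = small_binset.bins[10]
        assert (b10.start, b10.end) == (1_000_000, 1_100_000)
        assert ratio[10] == pytest.approx(0.75)

    def test_male_x_single_copy_doubles_on_gain(self, small_binset):
        ev = TruthEvent("X", 0, 1_000_000, "dup")
        ratio = copy_ratio([ev], small_binset, "male")
        xlo, _ = small_binset.chrom_slice("X")
        assert ratio[xlo] == pytest.approx(2.0)
        assert copy_ratio([ev], small_binset, "female")[xlo] == pytest.approx(1.5)

    def test_off_genome_event_rejected(self, small_binset):
        with pytest.raises(ValueError, match="off genome"):
            copy_ratio([TruthEvent("1", 0, 99_000_000, "del")], small_binset, "female")

    def test_contradictory_overlap_rejected(self, small_binset):
        a = TruthEvent("1", 1_000_000, 3_000_000, "del")
        b = TruthEvent("1", 2_000_000, 4_000_000, "dup")
        with pytest.raises(ValueError, match="contradictory"):
            copy_ratio([a, b], small_binset, "female")


class TestSimulateSample:
    def test_null_sample_tracks_expectation(self, small_config):
        cfg = replace(small_config, dispersion=0.0, gc_bias_amplitude=0.0,
                      panel_chrom_cv=0.0)
        row = simulate_sample([], cfg, "female", "null")
        mu = expected_profile([], cfg, "female")
        ok = mu > 0
        dev = (row.counts[ok] - mu[ok]) / np.sqrt(mu[ok])
        assert np.abs(dev).max() < 5.0

    def test_expected_autosomal_total_is_conserved(self, small_config):
        mu = expected_profile([], small_config, "male")
        auto = np.array([is_autosome(b.chrom) for b in small_config.binset.bins])
        assert mu[auto].sum() == pytest.approx(small_config.mean_filtered_reads, rel=1e-6)
        # an aneuploid genome adds exactly its copy-ratio mass
        ev = TruthEvent.whole_chrom("2", "whole_chrom_gain", 1.0, SMALL_SIZES)
        mu_tri = expected_profile([ev], small_config, "male")
        mass = 0.5 * 8 / 20  # half-copy gain over 8 of 20 autosomal Mb
        assert mu_tri[auto].sum() == pytest.approx(
            small_config.mean_filtered_reads * (1 + mass), rel=0.01
        )

    def test_same_seed_reproduces_and_is_order_independent(self, small_config):
        a = simulate_sample([], small_config, "female", "s1")
        b = simulate_sample([], small_config, "female", "s1")
        assert np.array_equal(a.counts, b.counts)
        # a different sample id yields an independent stream
        c = simulate_sample([], small_config, "female", "s2")
        assert not np.array_equal(a.counts, c.counts)

    def test_filtered_mapped_fraction_matches_mode(self, small_config):
        row = simulate_sample([], small_config, "female", "q")
        assert 100 * row.filtered_mapped / row.total_reads == pytest.approx(77.35, abs=0.01)
        wga = simulate_sample([], small_config.with_wga(), "female", "q")
        assert 100 * wga.filtered_mapped / wga.total_reads == pytest.approx(57.9, abs=0.01)

    def test_female_y_bins_are_empty(self, small_config):
        row = simulate_sample([], small_config, "female", "fy")
        ylo, yhi = small_config.binset.chrom_slice("Y")
        assert row.counts[ylo:yhi].sum() == 0


class TestSimulatePanel:
    def test_even_sex_split_and_reproducibility(self, small_config):
        panel = simulate_panel(small_config, n=20)
        sexes = [r.sex for r in panel.rows]
        assert sexes.count("male") == 10 and sexes.count("female") == 10
        again = simulate_panel(small_config, n=20)
        assert all(
            np.array_equal(a.counts, b.counts) for a, b in zip(panel.rows, again.rows)
        )

    def test_odd_n_with_strict_even_split_rejected(self, small_config):
        with pytest.raises(ValueError, match="50/50"):
            simulate_panel(small_config, n=21)

    def test_chromosome_share_cv_near_configured_value(self, small_config):
        panel = simulate_panel(small_config, n=40)
        chroms = np.array([b.chrom for b in small_config.binset.bins])
        auto = np.isin(chroms, ["1", "2"])
        shares = []
        for r in panel.rows:
            shares.append(r.counts[chroms == "1"].sum() / r.counts[auto].sum())
        cv = np.std(shares) / np.mean(shares)
        # chr2's independent factor also perturbs the denominator share
        assert small_config.panel_chrom_cv * 0.5 < cv < small_config.panel_chrom_cv * 2

    def test_wga_mode_attenuates_cnv_z_scores(self, small_config, small_binset):
        # paired cohorts, identical truth: WGA must lower mean |Z| on CNV bins
        from dkaryo.pipeline import PanelBundle
        from dkaryo.reference_panel import zscore_sample

        ev = TruthEvent("1", 2_000_000, 4_000_000, "del")
        inside = np.array(
            [b.chrom == "1" and b.start >= 2_000_000 and b.end <= 4_000_000
             for b in small_binset.bins]
        )
        means = {}
        for mode in (False, True):
            cfg = replace(small_config, wga_mode=mode, seed=77)
            panel = simulate_panel(cfg, n=30)
            bundle = PanelBundle.fit(panel, small_binset, SMALL_SIZES)
            zs = []
            for rep in range(10):
                row = simulate_sample([ev], cfg, "female", f"w{mode}-{rep}")
                z = zscore_sample(row, bundle.zpanel).z
                zs.append(np.nanmean(np.abs(z[inside])))
            means[mode] = np.mean(zs)
        assert means[True] < means[False]

    def test_wga_terminal_dropout_suppresses_terminal_signal(self, small_config):
        # expected counts in the last bins of each chromosome drop under WGA
        cfg = replace(small_config, seed=5)
        rows_wga = [
            simulate_sample([], cfg.with_wga(), "female", f"t{r}") for r in range(15)
        ]
        rows_std = [simulate_sample([], cfg, "female", f"t{r}") for r in range(15)]
        lo, hi = cfg.binset.chrom_slice("1")
        term_wga = np.mean([r.counts[hi - 5 : hi].mean() for r in rows_wga])
        term_std = np.mean([r.counts[hi - 5 : hi].mean() for r in rows_std])
        body_wga = np.mean([r.counts[lo : lo + 50].mean() for r in rows_wga])
        body_std = np.mean([r.counts[lo : lo + 50].mean() for r in rows_std])
        assert term_wga / term_std < 0.7  # dropout hits chromosome ends
        assert body_wga / body_std > 0.9  # chromosome bodies barely change


class TestTable1Fixture:
    def test_contains_21_cases_and_27_cnv_rows(self):
        # 16 single-CNV cases plus multi-CNV cases with 2, 2, 2, 3 and 2 rows
        fix = table1_fixture()
        assert len(fix) == 21
        assert sum(len(c.events) for c in fix) == 27

    def test_printed_sizes_match_coordinates_except_documented_rows(self):
        for case in table1_fixture():
            for fe in case.events:
                computed_kb = fe.event.size / 1000
                if fe.size_discrepant:
                    assert abs(computed_kb - fe.printed_size_kb) > 100
                else:
                    assert computed_kb == pytest.approx(fe.printed_size_kb, abs=100)

    def test_terminal_deletion_case_coordinates(self):
        pre6 = next(c for c in table1_fixture() if c.case_id == "pre-6")
        ev = pre6.events[0].event
        assert (ev.chrom, ev.start, ev.end) == ("1", 247_001_499, 249_224_684)
        assert ev.size == pytest.approx(2_200_000, abs=100_000)
        # terminal: ends within 30 kb of the chromosome end
        assert GRCH37_SIZES["1"] - ev.end < 30_000

    def test_mosaic_annotations_carried(self):
        pre13 = next(c for c in table1_fixture() if c.case_id == "pre-13")
        fractions = sorted(fe.event.fraction for fe in pre13.events)
        assert fractions == [0.5, 1.0]

    def test_sex_assignments_respect_copy_number_semantics(self):
        fix = {c.case_id: c for c in table1_fixture()}
        assert fix["pre-19"].sex == "male"  # X x2 is a gain only in a male
        assert fix["pre-20"].sex == "female"  # X x1 is a het loss only in a female

    def test_smallest_events_are_sub_bin(self):
        sizes = sorted(
            fe.printed_size_kb for c in table1_fixture() for fe in c.events
        )
        assert sizes[:2] == [220, 221]
        assert sizes[2] == 855


def test_truth_tsv_round_trip(tmp_path):
    truth = [
        TruthEvent("1", 100, 5_000_000, "del"),
        TruthEvent("2", 0, 8_000_000, "whole_chrom_gain", 0.3),
    ]
    path = tmp_path / "truth.tsv"
    write_truth_tsv(truth, path)
    assert read_truth_tsv(path) == truth
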