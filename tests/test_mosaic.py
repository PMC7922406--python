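import math

import numpy as np
import pytest

from dkaryo.depth_counts import CountMatrix, CountRow
from dkaryo.mosaic import (
    GAIN_M_MIN,
    LOSS_M_MIN,
    build_mb_grid,
    comparative_z,
    estimate_fraction,
    fit_mosaic_reference,
    flag_mosaics,
    log2_profile,
)
from dkaryo.genome_bins import build_bins
from dkaryo.simulate import SimConfig, TruthEvent, simulate_panel, simulate_sample, synthetic_gc

# The aberrant chromosome must be a minority of the autosome (as in a real
# genome) or the sample's own autosomal-median normalization absorbs part of
# the signal; chr2 here is 12/72 Mb of autosomal territory.
MO_SIZES = {"1": 60_000_000, "2": 12_000_000, "X": 10_000_000, "Y": 4_000_000}


@pytest.fixture(scope="module")
def mo_binset():
    bs = build_bins(MO_SIZES, None, 100_000)
    return bs.with_gc(list(synthetic_gc(bs)))


@pytest.fixture(scope="module")
def mo_config(mo_binset):
    return SimConfig(binset=mo_binset, mean_filtered_reads=500_000, seed=11,
                     chrom_sizes=dict(MO_SIZES))


@pytest.fixture(scope="module")
def mo_panel(mo_config):
    return simulate_panel(mo_config, n=40)


@pytest.fixture(scope="module")
def mosaic_ref(mo_panel, mo_binset):
    return fit_mosaic_reference(mo_panel, mo_binset, MO_SIZES)


class TestEstimateFraction:
    @pytest.mark.parametrize("f", [0.1 * k for k in range(1, 11)])
    @pytest.mark.parametrize("direction", ["gain", "loss"])
    def test_inverts_the_forward_copy_ratio_model_exactly(self, f, direction):
        # forward model: a fraction f of cells carries one extra/missing copy
        ratio = 1 + f / 2 if direction == "gain" else 1 - f / 2
        m = math.log2(ratio)
        assert estimate_fraction(m, direction) == pytest.approx(f, abs=1e-12)

    def test_landmark_values(self):
        assert estimate_fraction(math.log2(1.4), "gain") == pytest.approx(0.80)
        assert estimate_fraction(0.0, "gain") == 0.0
        assert estimate_fraction(-1.0, "loss") == 1.0

    def test_direction_sign_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            estimate_fraction(-0.2, "gain")
        with pytest.raises(ValueError):
            estimate_fraction(0.2, "loss")

    def test_out_of_range_ratio_clips_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="dkaryo"):
            assert estimate_fraction(-1.4, "loss") == 1.0
        assert any("clipping" in r.message for r in caplog.records)


class TestLog2Profile:
    def test_panel_median_profile_scores_near_zero(self, mo_panel, mosaic_ref):
        profile = log2_profile(mo_panel.rows[0], mosaic_ref)
        auto = [profile.per_chrom_median[c] for c in ("1", "2")]
        assert max(abs(v) for v in auto) < 0.05

    def test_full_trisomy_hits_log2_of_three_halves(self, mo_config, mosaic_ref):
        ev = TruthEvent.whole_chrom("2", "whole_chrom_gain", 1.0, MO_SIZES)
        row = simulate_sample([ev], mo_config, "female", "tri2")
        profile = log2_profile(row, mosaic_ref)
        assert profile.chrom_m("2") == pytest.approx(math.log2(1.5), abs=0.04)
        assert abs(profile.chrom_m("1")) < 0.04

    def test_full_monosomy_hits_minus_one(self, mo_config, mosaic_ref):
        ev = TruthEvent.whole_chrom("2", "whole_chrom_loss", 1.0, MO_SIZES)
        row = simulate_sample([ev], mo_config, "female", "mono2")
        profile = log2_profile(row, mosaic_ref)
        assert profile.chrom_m("2") == pytest.approx(-1.0, abs=0.06)

    def test_all_zero_sample_is_an_error(self, mosaic_ref, mo_binset):
        row = CountRow("z", "female", np.zeros(len(mo_binset), dtype=int), 1, 1)
        with pytest.raises(ValueError):
            log2_profile(row, mosaic_ref)


class TestComparativeZ:
    def test_panel_member_scores_near_zero(self, mo_panel, mosaic_ref):
        zc = comparative_z(mo_panel.rows[3], mosaic_ref)
        assert abs(zc["1"]) < 3.5  # a panel member is typical of the panel

    def test_leave_one_out_sd_close_to_one(self, mo_panel, mo_binset):
        zs = {c: [] for c in ("1", "2")}
        for i in range(len(mo_panel.rows)):
            rest = CountMatrix(
                mo_panel.rows[:i] + mo_panel.rows[i + 1:],
                mo_panel.binset_checksum,
            )
            ref = fit_mosaic_reference(rest, mo_binset, MO_SIZES)
            zc = comparative_z(mo_panel.rows[i], ref)
            for c in zs:
                zs[c].append(zc[c])
        for c, vals in zs.items():
            assert 0.85 < np.std(vals) < 1.15, c

    def test_ten_percent_trisomy_with_one_percent_cv_panel_scores_about_five(self):
        # constructed panel: chromosome share mean 0.03, sd 1% of that
        from dkaryo.mosaic import MosaicReference, MbGrid

        rng = np.random.default_rng(0)
        # reuse a tiny grid: one chromosome pair
        from dkaryo.genome_bins import build_bins

        bs = build_bins({"1": 40_000_000, "2": 2_000_000}, None, 1_000_000)
        grid_sizes = {"1": 40_000_000, "2": 2_000_000}
        rows = []
        for i in range(100):
            base = np.array(
                [1000.0 if b.chrom == "1" else 1000.0 for b in bs.bins]
            )
            jitter = 1 + rng.normal(0, 0.01)
            counts = np.array(
                [c * (jitter if b.chrom == "2" else 1.0) for c, b in zip(base, bs.bins)]
            ).astype(int)
            rows.append(CountRow(f"c{i}", "female", counts, int(counts.sum()), int(counts.sum())))
        ref = fit_mosaic_reference(CountMatrix(rows, bs.checksum), bs, grid_sizes)
        test = np.array([1000] * 40 + [1050, 1050], dtype=int)  # x1.05 on chr2
        row = CountRow("t", "female", test, int(test.sum()), int(test.sum()))
        zc = comparative_z(row, ref)
        assert zc["2"] == pytest.approx(5.0, abs=1.5)

    def test_z_magnitude_monotone_in_mosaic_fraction(self, mo_config, mosaic_ref):
        prev = 0.0
        for f in (0.2, 0.5, 1.0):
            ev = TruthEvent.whole_chrom("2", "whole_chrom_loss", f, MO_SIZES)
            row = simulate_sample([ev], mo_config, "female", f"mono-{f}")
            z = comparative_z(row, mosaic_ref)["2"]
            assert z < 0 and abs(z) > abs(prev)
            prev = z


class TestFlagMosaics:
    def flags(self, truth, config, ref, sample_id, sex="female"):
        row = simulate_sample(truth, config, sex, sample_id)
        profile = log2_profile(row, ref)
        zc = comparative_z(row, ref)
        return flag_mosaics(profile, zc)

    def test_full_aneuploidy_flagged_by_both_statistics(self, mo_config, mosaic_ref):
        ev = TruthEvent.whole_chrom("2", "whole_chrom_gain", 1.0, MO_SIZES)
        calls = [m for m in self.flags([ev], mo_config, mosaic_ref, "full2") if m.chrom == "2"]
        assert len(calls) == 1
        assert calls[0].flagged_by == frozenset({"log2", "comparative"})
        assert calls[0].direction == "gain"
        assert calls[0].fraction == pytest.approx(1.0, abs=0.1)

    def test_eighty_percent_gain_recovers_fraction(self, mo_config, mosaic_ref):
        ev = TruthEvent.whole_chrom("2", "whole_chrom_gain", 0.8, MO_SIZES)
        calls = [m for m in self.flags([ev], mo_config, mosaic_ref, "mo5") if m.chrom == "2"]
        assert calls and calls[0].fraction == pytest.approx(0.8, abs=0.07)

    def test_segmental_mosaic_reported_with_coordinates(self, mo_config, mosaic_ref):
        # 6 Mb of a 12 Mb chromosome at 60% gain: segmental, not whole-chromosome
        ev = TruthEvent("1", 2_000_000, 8_000_000, "dup", 0.6)
        calls = [m for m in self.flags([ev], mo_config, mosaic_ref, "seg") if m.chrom == "1"]
        seg = [m for m in calls if m.start is not None]
        assert seg, calls
        assert seg[0].start <= 2_500_000 and seg[0].end >= 7_500_000
        assert seg[0].direction == "gain"
        assert seg[0].fraction == pytest.approx(0.6, abs=0.15)

    def test_fraction_recovery_unbiased_for_f_at_least_point_two(
        self, mo_config, mosaic_ref
    ):
        from dataclasses import replace

        for f in (0.2, 0.5, 1.0):
            est = []
            for rep in range(20):
                cfg = replace(mo_config, seed=mo_config.seed + 100 + rep)
                ev = TruthEvent.whole_chrom("2", "whole_chrom_gain", f, MO_SIZES)
                row = simulate_sample([ev], cfg, "female", f"rec-{f}-{rep}")
                profile = log2_profile(row, mosaic_ref)
                est.append(estimate_fraction(max(profile.chrom_m("2"), 0.0), "gain"))
            assert np.mean(est) == pytest.approx(f, abs=0.05)
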