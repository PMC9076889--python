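import numpy as np
import numpy.ma as ma
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import forkhist as fh
from forkhist.bias import StrandedBinTrack
from forkhist.simulate import GENOTYPE_PRESETS, SimulationConfig, TransferParams

from conftest import random_reads


def track_from_counts(w, c, bin_width=5000):
    w = np.asarray(w, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    return StrandedBinTrack(bin_width, {"chr1": w}, {"chr1": c})


class TestCounting:
    def test_midpoint_rule_places_read_in_one_bin(self, toy_genome):
        read = fh.StrandedRead("chr1", 5_100, 9_700, "W", "espan")  # midpoint 7400
        track = fh.count_stranded_reads([read], toy_genome, bin_width=5000)
        assert track.watson["chr1"][1] == 1
        assert track.watson["chr1"].sum() == 1 and track.crick["chr1"].sum() == 0

    def test_counts_match_one_read_at_a_time_oracle(self, toy_genome, rng):
        reads = random_reads(toy_genome, rng, 1000)
        track = fh.count_stranded_reads(reads, toy_genome, bin_width=5000)
        tally = {}
        for r in reads:
            key = (r.chrom, (r.start + r.end) // 2 // 5000, r.strand)
            tally[key] = tally.get(key, 0) + 1
        for (chrom, b, strand), n in tally.items():
            arr = track.watson if strand == "W" else track.crick
            assert arr[chrom][b] == n
        assert track.n_assigned == len(reads)

    def test_unknown_chromosome_error_lists_records(self, toy_genome):
        bad = fh.StrandedRead("chrZ", 100, 200, "W", "espan")
        with pytest.raises(ValueError, match="chrZ:100-200"):
            fh.count_stranded_reads([bad], toy_genome)

    def test_reads_beyond_chromosome_end_rejected_with_count(self, toy_genome):
        beyond = fh.StrandedRead("chr1", 999_990, 1_000_090, "W", "espan")
        track = fh.count_stranded_reads([beyond], toy_genome)
        assert track.n_rejected == 1 and track.n_assigned == 0


class TestBiasStatistic:
    @pytest.mark.parametrize("w,c,expected", [
        (5, 5, 0.0),        # symmetric counts
        (6, 2, 0.5),        # (6-2)/(6+2)
        (4, 0, 1.0),        # one-sided at threshold
        (0, 7, -1.0),
    ])
    def test_bias_values(self, w, c, expected):
        bias = fh.compute_bias(track_from_counts([w], [c]))
        assert bias.values["chr1"][0] == expected

    def test_low_coverage_bins_masked_not_zeroed(self):
        bias = fh.compute_bias(track_from_counts([3, 2, 0], [0, 1, 0]))
        assert ma.getmaskarray(bias.values["chr1"]).all()

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)),
                    min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_range_and_filter_invariants(self, counts):
        w = [a for a, _ in counts]
        c = [b for _, b in counts]
        bias = fh.compute_bias(track_from_counts(w, c), min_reads=4)
        v = bias.values["chr1"]
        mask = ma.getmaskarray(v)
        for i, (wi, ci) in enumerate(zip(w, c)):
            if wi + ci < 4:
                assert mask[i]
            else:
                assert not mask[i]
                assert -1.0 <= v[i] <= 1.0
                assert (abs(v[i]) == 1.0) == (wi == 0 or ci == 0)


class TestNormalization:
    def test_zero_control_is_identity(self):
        espan = fh.compute_bias(track_from_counts([6, 10], [2, 10]))
        control = fh.compute_bias(track_from_counts([5, 8], [5, 8]))
        out = fh.normalize_bias(espan, control)
        assert np.allclose(out.values["chr1"], espan.values["chr1"])
        assert out.provenance[-1] == "normalized"

    def test_subtraction_rule(self):
        espan = fh.compute_bias(track_from_counts([13], [7]))    # 0.3
        control = fh.compute_bias(track_from_counts([11], [9]))  # 0.1
        out = fh.normalize_bias(espan, control)
        assert out.values["chr1"][0] == pytest.approx(0.2)

    def test_mask_propagates_from_either_input(self):
        espan = fh.compute_bias(track_from_counts([6, 6], [2, 2]))
        control = fh.compute_bias(track_from_counts([5, 1], [5, 1]))  # bin 1 masked
        out = fh.normalize_bias(espan, control)
        assert not ma.getmaskarray(out.values["chr1"])[0]
        assert ma.getmaskarray(out.values["chr1"])[1]

    def test_shape_mismatch_rejected(self):
        a = fh.compute_bias(track_from_counts([6, 6], [2, 2]))
        b = fh.compute_bias(track_from_counts([6], [2]))
        with pytest.raises(ValueError, match="mismatch"):
            fh.normalize_bias(a, b)


class TestSmoothing:
    def constant_track(self, value, n=40):
        w = np.full(n, 10)
        bias = fh.compute_bias(track_from_counts(w, w))
        for chrom in bias.values:
            bias.values[chrom] = ma.MaskedArray(np.full(n, value), mask=False)
        return bias

    def test_constant_track_unchanged(self):
        out = fh.smooth_bias(self.constant_track(0.3))
        assert np.allclose(out.values["chr1"], 0.3)

    def test_unit_impulse_matches_brute_force_window_mean(self):
        track = self.constant_track(0.0, n=31)
        track.values["chr1"][15] = 1.0
        out = fh.smooth_bias(track, flank_bins=5)
        v = track.values["chr1"].data
        oracle = np.array([
            np.mean(v[max(0, i - 5): i + 6]) for i in range(31)
        ])
        assert np.allclose(out.values["chr1"], oracle)
        assert out.values["chr1"][15] == pytest.approx(1 / 11)

    def test_zero_flank_is_identity(self):
        track = self.constant_track(0.0, n=10)
        track.values["chr1"][4] = 0.7
        out = fh.smooth_bias(track, flank_bins=0)
        assert np.allclose(out.values["chr1"], track.values["chr1"])
        assert out.provenance[-1] == "smoothed"

    def test_fully_masked_window_stays_masked(self):
        track = self.constant_track(0.2, n=30)
        track.values["chr1"][5:25] = ma.masked
        out = fh.smooth_bias(track, flank_bins=2)
        assert ma.getmaskarray(out.values["chr1"])[10:20].all()
        # bins adjacent to unmasked data get a value from the partial window
        assert not ma.getmaskarray(out.values["chr1"])[6]


class TestOriginAggregation:
    def antisymmetric_bias(self, origin_pos=500_000, value=0.4, bin_width=5000,
                           n_bins=200):
        v = np.zeros(n_bins)
        center = origin_pos // bin_width
        v[:center] = -value
        v[center + 1:] = value
        return fh.BiasTrack(bin_width, {"chr1": ma.MaskedArray(v, mask=False)},
                            min_reads=4)

    def test_zero_bias_gives_zero_profile(self):
        track = self.antisymmetric_bias(value=0.0)
        origins = [fh.Origin("chr1", 500_000, 0.8)]
        profile = fh.aggregate_origins(track, origins, flank_bp=40_000)
        assert np.allclose(profile.mean_bias, 0.0)
        assert fh.leading_bias_score(profile) == 0.0

    def test_single_origin_antisymmetric_profile_and_score(self):
        track = self.antisymmetric_bias(value=0.4)
        origins = [fh.Origin("chr1", 500_000, 0.8)]
        profile = fh.aggregate_origins(track, origins, flank_bp=40_000)
        left = profile.mean_bias[profile.offsets < 0]
        right = profile.mean_bias[profile.offsets > 0]
        assert np.allclose(left, -0.4) and np.allclose(right, 0.4)
        assert fh.leading_bias_score(profile) == pytest.approx(0.4)

    def test_matrix_rows_ranked_by_descending_efficiency(self, toy_genome):
        track = fh.BiasTrack(5000, {
            c: ma.MaskedArray(np.zeros(200), mask=False)
            for c, _ in toy_genome.chromosomes
        }, min_reads=4)
        profile = fh.aggregate_origins(track, toy_genome.origins, flank_bp=20_000)
        assert profile.n_origins == len(toy_genome.origins)
        assert (np.diff(profile.efficiencies) <= 0).all()

    def test_flank_must_be_bin_multiple(self):
        track = self.antisymmetric_bias()
        with pytest.raises(ValueError, match="multiple"):
            fh.aggregate_origins(track, [fh.Origin("chr1", 500_000, 1.0)], 7_500)


def full_chain_score(genome, p_leading, seed, n_cells=6):
    params = TransferParams("probe", p_leading=p_leading, retain_prob=1.0)
    cfg = SimulationConfig(seed=seed, n_cells=n_cells)
    espan, brdu = fh.simulate_espan(genome, params, cfg)
    b = fh.compute_bias(fh.count_stranded_reads(espan, genome))
    ctrl = fh.compute_bias(fh.count_stranded_reads(brdu, genome))
    smooth = fh.smooth_bias(fh.normalize_bias(b, ctrl))
    profile = fh.aggregate_origins(smooth, genome.origins, 40_000)
    return fh.leading_bias_score(profile)


class TestFullChain:
    def test_full_leading_deposition_gives_antisymmetric_smoothed_profile(self, toy_genome):
        params = TransferParams("forced", p_leading=1.0, retain_prob=1.0)
        cfg = SimulationConfig(seed=6, n_cells=4)
        espan, brdu = fh.simulate_espan(toy_genome, params, cfg)
        b = fh.compute_bias(fh.count_stranded_reads(espan, toy_genome))
        ctrl = fh.compute_bias(fh.count_stranded_reads(brdu, toy_genome))
        smooth = fh.smooth_bias(fh.normalize_bias(b, ctrl))
        profile = fh.aggregate_origins(smooth, toy_genome.origins, 40_000)
        mean = profile.mean_bias
        assert (mean[profile.offsets >= 10_000] > 0).all()
        assert (mean[profile.offsets <= -10_000] < 0).all()

    def test_score_increases_with_leading_strand_probability(self, toy_genome):
        scores = [full_chain_score(toy_genome, p, seed=31) for p in (0.3, 0.5, 0.7)]
        assert scores[0] < scores[1] < scores[2]

    def test_randomly_stranded_bulk_reads_show_no_origin_bias(self, toy_genome):
        """Bulk chromatin profiling reads carry no fork strand information."""
        cfg = SimulationConfig(seed=17, n_reads=50_000)
        sample = fh.simulate_cutrun_timecourse(toy_genome, [0.0], {0.0: 0.0}, cfg)[0.0]
        b = fh.compute_bias(fh.count_stranded_reads(sample.mouse_reads, toy_genome))
        profile = fh.aggregate_origins(fh.smooth_bias(b), toy_genome.origins, 40_000)
        assert abs(fh.leading_bias_score(profile)) < 0.05
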