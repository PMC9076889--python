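import numpy as np
import pytest

import forkhist as fh
from forkhist.coverage import BinnedCounts, DensityTrack, _interval_mean
from forkhist.genome import GeneModel
from forkhist.simulate import SimulationConfig


def counts_from(arrays, bin_width=1000):
    return BinnedCounts(bin_width, {c: np.asarray(v, dtype=np.int64)
                                    for c, v in arrays.items()})


def density_from(arrays, bin_width=1000, normalization="rpm"):
    return DensityTrack(bin_width, {c: np.asarray(v, dtype=float)
                                    for c, v in arrays.items()},
                        normalization, 1.0, 1)


class TestNormalizations:
    def test_rpm_factor_one_at_million_reads(self):
        track = fh.rpm_normalize(counts_from({"chr1": [3, 7, 0]}), 1_000_000)
        assert np.array_equal(track.data["chr1"], [3.0, 7.0, 0.0])
        assert track.scale_factor == 1.0

    def test_rpm_scale_invariance(self):
        a = fh.rpm_normalize(counts_from({"chr1": [4, 8]}), 200_000)
        b = fh.rpm_normalize(counts_from({"chr1": [8, 16]}), 400_000)
        assert np.allclose(a.data["chr1"], b.data["chr1"])

    def test_rpm_example_value(self):
        track = fh.rpm_normalize(counts_from({"chr1": [4]}), 250_000)
        assert track.data["chr1"][0] == 16.0

    def test_rpm_rejects_zero_library(self):
        with pytest.raises(ValueError):
            fh.rpm_normalize(counts_from({"chr1": [1]}), 0)

    @pytest.mark.parametrize("human", [1, 250_000, 1_000_000, 3_333_333])
    def test_spikein_scale_identity(self, human):
        track = fh.spikein_normalize(counts_from({"chr1": [5]}), human)
        # algebraic identity; exact in floats when the division is (as in
        # the canonical 250,000 -> 4 case), within 1 ulp otherwise
        if human in (1, 250_000, 1_000_000):
            assert track.scale_factor * human == 1_000_000.0
        else:
            assert track.scale_factor * human == pytest.approx(1_000_000.0, rel=1e-12)
        assert track.normalization == "spikein"

    def test_spikein_linearity_in_mouse_counts(self):
        a = fh.spikein_normalize(counts_from({"chr1": [3, 6]}), 50_000)
        b = fh.spikein_normalize(counts_from({"chr1": [6, 12]}), 50_000)
        assert np.allclose(b.data["chr1"], 2 * a.data["chr1"])


class TestMetagene:
    def test_uniform_density_gives_flat_equal_quartiles(self):
        genes = [GeneModel("chr1", 10_000 + i * 20_000, 20_000 + i * 20_000,
                           "+" if i % 2 else "-", q, float(q))
                 for i, q in enumerate((1, 2, 3, 4))]
        density = density_from({"chr1": np.full(100, 2.5)})
        prof = fh.metagene_profile(density, genes, n_scaled_bins=10, flank_bp=2000,
                                   n_flank_bins=4)
        for q in (1, 2, 3, 4):
            assert np.allclose(prof.by_quartile[q], 2.5)

    def test_single_gene_body_indicator(self):
        # gene aligned to the bin grid: density 1 inside the body, 0 outside
        gene = GeneModel("chr1", 20_000, 30_000, "+", 4, 4.0)
        values = np.zeros(50)
        values[20:30] = 1.0
        density = density_from({"chr1": values})
        prof = fh.metagene_profile(density, [gene], n_scaled_bins=10,
                                   flank_bp=2000, n_flank_bins=2)
        out = prof.by_quartile[4]
        assert np.allclose(out[prof.body_slice()], 1.0)
        assert np.allclose(out[: prof.n_flank_bins], 0.0)
        assert np.allclose(out[-prof.n_flank_bins:], 0.0)

    def test_minus_strand_gene_is_flipped_to_transcriptional_orientation(self):
        # step density rising along the genome; a minus-strand gene must
        # therefore *fall* from its TSS to its TTS
        gene = GeneModel("chr1", 20_000, 30_000, "-", 2, 1.0)
        density = density_from({"chr1": np.arange(50, dtype=float)})
        prof = fh.metagene_profile(density, [gene], n_scaled_bins=10,
                                   flank_bp=2000, n_flank_bins=2)
        body = prof.by_quartile[2][prof.body_slice()]
        assert (np.diff(body) < 0).all()

    def test_short_genes_excluded_with_count(self):
        gene = GeneModel("chr1", 100, 600, "+", 1, 0.5)  # shorter than one bin
        density = density_from({"chr1": np.ones(50)})
        prof = fh.metagene_profile(density, [gene], n_scaled_bins=5)
        assert prof.n_excluded == 1 and prof.gene_counts[1] == 0

    def test_profile_mean_matches_brute_force_per_bp_oracle(self, rng):
        """Scaled-body segment means agree with a per-bp expansion."""
        bin_width = 100
        values = rng.random(500)  # 50 kb chromosome
        density = density_from({"chr1": values}, bin_width=bin_width)
        gene = GeneModel("chr1", 12_345, 31_234, "+", 3, 2.0)
        n_scaled = 20
        prof = fh.metagene_profile(density, [gene], n_scaled_bins=n_scaled,
                                   flank_bp=1000, n_flank_bins=5)
        per_bp = np.repeat(values, bin_width)
        edges = np.linspace(gene.tss, gene.tts, n_scaled + 1)
        oracle = []
        for a, b in zip(edges[:-1], edges[1:]):
            ia, ib = int(np.floor(a)), int(np.ceil(b))
            w = np.ones(ib - ia)
            w[0] -= a - ia
            w[-1] -= ib - b
            oracle.append((per_bp[ia:ib] * w).sum() / w.sum())
        assert np.allclose(prof.by_quartile[3][prof.body_slice()], oracle)

    def test_simulated_quartile_ordering(self, toy_genome):
        """H3.3-weighted sampling yields body densities ordered Q4 > ... > Q1."""
        cfg = SimulationConfig(seed=5, n_reads=80_000)
        sample = fh.simulate_cutrun_timecourse(toy_genome, [0.0], {0.0: 0.0}, cfg)[0.0]
        counts = fh.bin_reads(sample.mouse_reads, toy_genome, 1000)
        density = fh.rpm_normalize(counts, sample.mouse_library_size)
        prof = fh.metagene_profile(density, toy_genome.genes)
        means = [prof.mean_body_density(q) for q in (1, 2, 3, 4)]
        assert means[0] < means[1] < means[2] < means[3]


class TestRegionDensity:
    def test_constant_density_gives_constant_region_means(self):
        density = density_from({"chr1": np.full(100, 3.0)})
        table = fh.region_density(density, [("chr1", 1_000, 5_000),
                                            ("chr1", 50_500, 61_700)])
        assert np.allclose(table["mean_density"], 3.0)

    def test_region_outside_genome_is_named_in_error(self):
        density = density_from({"chr1": np.ones(10)})
        with pytest.raises(ValueError, match="chr1:5000-999000"):
            fh.region_density(density, [("chr1", 5_000, 999_000)])

    def test_partial_bin_overlap_is_length_weighted(self):
        density = density_from({"chr1": np.array([2.0, 4.0])}, bin_width=1000)
        table = fh.region_density(density, [("chr1", 500, 1_500)])
        assert table["mean_density"][0] == pytest.approx(3.0)


class TestCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.poisson(5.0, 40).astype(float)
        t1 = density_from({"chr1": x}, bin_width=5000)
        t2 = density_from({"chr1": x.copy()}, bin_width=5000)
        corr = fh.correlation_matrix([t1, t2], window_bp=10_000)
        assert np.allclose(corr.to_numpy(), 1.0)

    def test_negation_about_mean_gives_minus_one(self, rng):
        x = rng.random(40) + 1.0
        t1 = density_from({"chr1": x}, bin_width=5000)
        t2 = density_from({"chr1": 2 * x.mean() - x}, bin_width=5000)
        corr = fh.correlation_matrix([t1, t2], window_bp=10_000)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_replicates_with_independent_sampling_noise_correlate(self, toy_genome):
        cfg1 = SimulationConfig(seed=100, n_reads=60_000)
        cfg2 = SimulationConfig(seed=200, n_reads=60_000)
        s1 = fh.simulate_cutrun_timecourse(toy_genome, [0.0], {0.0: 0.0}, cfg1)[0.0]
        s2 = fh.simulate_cutrun_timecourse(toy_genome, [0.0], {0.0: 0.0}, cfg2)[0.0]
        tracks = [fh.rpm_normalize(fh.bin_reads(s.mouse_reads, toy_genome, 1000),
                                   s.mouse_library_size) for s in (s1, s2)]
        corr = fh.correlation_matrix(tracks, window_bp=50_000)
        assert corr.iloc[0, 1] > 0.9

    def test_fewer_than_two_tracks_rejected(self):
        t = density_from({"chr1": np.ones(10)})
        with pytest.raises(ValueError):
            fh.correlation_matrix([t])


def test_interval_mean_is_length_weighted():
    v = np.array([1.0, 3.0])
    assert _interval_mean(v, 1000, 500, 1500) == pytest.approx(2.0)
    assert _interval_mean(v, 1000, 0, 1000) == 1.0
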