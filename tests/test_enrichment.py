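"""Overlap scoring and the density-preserving shuffle null."""

import numpy as np
import pytest
from scipy import stats

from insertion_fate.core import GenomeSpec, InsertionSet, IntervalSet
from insertion_fate.coverage import CoverageProfile
from insertion_fate.enrichment import (
    density_preserving_shuffle,
    enrichment_z,
    flank_coverage_enrichment,
    overlap_score,
)


@pytest.fixture()
def g100():
    return GenomeSpec(100, 0, 50)


def uniform_background(genome, k=20):
    width = genome.length_bp / k
    centers = (np.arange(k) + 0.5) * width
    return CoverageProfile(int(width), int(width), centers, np.ones(k), genome)


class TestOverlapScore:
    def test_empty_interval_set_scores_zero(self, g100):
        ins = InsertionSet([5, 15], genome=g100)
        empty = IntervalSet.from_records("none", [], g100)
        assert overlap_score(ins, empty) == 0.0

    def test_hand_count_without_flank(self, g100):
        ins = InsertionSet([5, 15, 25], genome=g100)
        iv = IntervalSet.from_records("x", [(10, 20)], g100)
        assert overlap_score(ins, iv, flank_bp=0) == 1.0

    def test_hand_count_with_flank_half_open(self, g100):
        # interval [10,20) extended by 5 -> [5,25): 5 and 15 in, 25 out
        ins = InsertionSet([5, 15, 25], genome=g100)
        iv = IntervalSet.from_records("x", [(10, 20)], g100)
        assert overlap_score(ins, iv, flank_bp=5) == 2.0

    def test_overlapping_intervals_merged_no_double_count(self, g100):
        ins = InsertionSet([12], genome=g100)
        iv = IntervalSet.from_records("x", [(10, 20), (11, 15)], g100)
        assert overlap_score(ins, iv) == 1.0

    def test_origin_crossing_feature_as_two_records(self, g100):
        # one feature spanning 95..5, stored split with a shared id
        ins = InsertionSet([98, 2], genome=g100)
        iv = IntervalSet.from_records("x", [(95, 100, "f"), (0, 5, "f")], g100)
        assert overlap_score(ins, iv) == 2.0

    def test_weights_counted(self, g100):
        ins = InsertionSet([12, 13], weights=[2.5, 4.0], genome=g100)
        iv = IntervalSet.from_records("x", [(10, 20)], g100)
        assert overlap_score(ins, iv) == 6.5

    def test_monotone_in_added_intervals(self, g100, rng):
        ins = InsertionSet(rng.integers(0, 100, 30), genome=g100)
        iv1 = IntervalSet.from_records("x", [(10, 20)], g100)
        iv2 = IntervalSet.from_records("x", [(10, 20), (40, 60)], g100)
        assert overlap_score(ins, iv2) >= overlap_score(ins, iv1)


class TestDensityPreservingShuffle:
    def test_zero_draws(self, g100):
        out = density_preserving_shuffle(0, uniform_background(g100), g100, seed=1)
        assert len(out) == 0

    def test_uniform_background_gives_uniform_positions(self):
        g = GenomeSpec(100_000, 0)
        bg = uniform_background(g, k=20)
        out = density_preserving_shuffle(100_000, bg, g, seed=7)
        counts, _ = np.histogram(out.positions, bins=20, range=(0, g.length_bp))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_point_mass_background(self, g100):
        values = np.zeros(20)
        values[3] = 1.0
        bg = uniform_background(g100, 20)
        bg = CoverageProfile(bg.window_bp, bg.step_bp, bg.centers, values, g100)
        out = density_preserving_shuffle(500, bg, g100, seed=2)
        lo = bg.bin_left_edges()[3]
        assert np.all((out.positions >= lo) & (out.positions < lo + bg.bin_widths()[3]))


class TestEnrichmentZ:
    def test_whole_genome_list_is_degenerate(self, g100):
        ins = InsertionSet([5, 15], genome=g100)
        iv = IntervalSet.from_records("all", [(0, 100)], g100)
        res = enrichment_z(ins, iv, uniform_background(g100), n_shuffles=50, seed=1)
        assert res.degenerate
        assert res.z is None

    def test_z_matches_binomial_oracle(self):
        # intervals cover 10% of the genome; 1000 insertions, 200 inside:
        # Z ~ (200-100)/sqrt(1000*0.1*0.9) ~ 10.54
        g = GenomeSpec(100_000, 0)
        iv = IntervalSet.from_records("t", [(10_000, 20_000)], g)
        rng = np.random.default_rng(5)
        inside = rng.integers(10_000, 20_000, 200)
        outside = (rng.integers(20_000, 110_000, 800)) % 100_000
        ins = InsertionSet(np.concatenate([inside, outside]), genome=g)
        zs = [
            enrichment_z(ins, iv, uniform_background(g), n_shuffles=2000, seed=s).z
            for s in range(3)
        ]
        assert np.mean(zs) == pytest.approx(10.54, abs=0.5)

    def test_null_draws_give_standard_normal_z(self):
        # insertions drawn from the background itself: Z approx N(0,1)
        g = GenomeSpec(100_000, 0)
        bg = uniform_background(g)
        rng = np.random.default_rng(11)
        zs = []
        for rep in range(60):
            s = int(rng.integers(0, 20_000))
            w = int(rng.integers(5_000, 15_000))
            iv = IntervalSet.from_records("l", [(s, s + w)], g)
            ins = density_preserving_shuffle(500, bg, g, seed=1000 + rep)
            zs.append(enrichment_z(ins, iv, bg, n_shuffles=400, seed=rep).z)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.5
        assert 0.5 < zs.std() < 1.6

    def test_sign_convention(self):
        g = GenomeSpec(100_000, 0)
        bg = uniform_background(g)
        iv = IntervalSet.from_records("t", [(10_000, 30_000)], g)
        rng = np.random.default_rng(3)
        enriched = InsertionSet(rng.integers(10_000, 30_000, 300), genome=g)
        depleted = InsertionSet(rng.integers(30_000, 100_000, 300), genome=g)
        assert enrichment_z(enriched, iv, bg, n_shuffles=300, seed=0).z > 0
        assert enrichment_z(depleted, iv, bg, n_shuffles=300, seed=0).z < 0

    def test_p_emp_has_add_one_correction(self):
        g = GenomeSpec(100_000, 0)
        bg = uniform_background(g)
        iv = IntervalSet.from_records("t", [(0, 10_000)], g)
        ins = InsertionSet(np.arange(0, 10_000, 20), genome=g)  # all inside
        res = enrichment_z(ins, iv, bg, n_shuffles=100, seed=0)
        assert res.p_emp == pytest.approx(1 / 101)


class TestFlankCoverage:
    def test_toy_half_covered_window(self):
        # L=100, window 10, insertion at 50, interval [50,55): window [45,55)
        g = GenomeSpec(100, 0, 50)
        ins = InsertionSet([50], genome=g)
        iv = IntervalSet.from_records("x", [(50, 55)], g)
        res = flank_coverage_enrichment(ins, iv, flank_bp=10,
                                        background=uniform_background(g), n_shuffles=50, seed=1)
        assert res.observed == pytest.approx(0.5)

    def test_whole_genome_interval_degenerate(self, g100):
        ins = InsertionSet([50], genome=g100)
        iv = IntervalSet.from_records("all", [(0, 100)], g100)
        res = flank_coverage_enrichment(ins, iv, flank_bp=10,
                                        background=uniform_background(g100), n_shuffles=50, seed=1)
        assert res.observed == 1.0
        assert res.degenerate

    def test_enrichment_detected_for_flank_hugging_intervals(self):
        g = GenomeSpec(100_000, 0)
        rng = np.random.default_rng(4)
        sites = rng.integers(0, 100_000, 40)
        # put an interval 2 kb downstream of each site (inside a 10 kb window)
        iv = IntervalSet.from_records(
            "near", [((int(s) + 1000) % 99_000, (int(s) + 2000) % 99_000 + 500) for s in sites
                     if (int(s) + 1000) % 99_000 < (int(s) + 2000) % 99_000], g)
        ins = InsertionSet(sites, genome=g)
        res = flank_coverage_enrichment(ins, iv, flank_bp=10_000,
                                        background=uniform_background(g),
                                        n_shuffles=300, seed=2)
        assert res.z > 3
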