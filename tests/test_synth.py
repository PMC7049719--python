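"""Synthetic world generators: genomes, insertions, clones, sorting, colonies."""

import numpy as np
import pytest
from scipy import stats

from insertion_fate.atcontent import at_fraction
from insertion_fate.coverage import sliding_coverage
from insertion_fate.dosage import dosage_prediction_for, fit_dosage_exponent
from insertion_fate.enrichment import _inside, _merged_segments
from insertion_fate.errors import ValidationError
from insertion_fate.lineage import sister_divergence
from insertion_fate.noise import clone_stats
from insertion_fate.synth import (
    SwitchParams,
    SynthConfig,
    assign_clone_phenotypes,
    make_genome,
    sample_cell_expression,
    sample_insertions,
    simulate_microcolony,
    sort_population,
)


class TestMakeGenome:
    def test_deterministic_given_seed(self, synth_config):
        a = make_genome(synth_config, seed=5)
        b = make_genome(synth_config, seed=5)
        assert a.sequence == b.sequence
        for name in a.intervals:
            assert a.intervals[name].records() == b.intervals[name].records()

    def test_seven_rrn_operons_by_default(self, synth_world):
        ann, _ = synth_world
        assert len(ann.intervals["rrn"]) == 7

    def test_background_at_level_without_islands(self):
        cfg = SynthConfig(length_bp=200_000, at_island_count=0, seed=3)
        ann = make_genome(cfg)
        assert at_fraction(ann.sequence) == pytest.approx(cfg.background_at, abs=0.01)

    def test_islands_are_at_rich(self, synth_world, synth_config):
        ann, _ = synth_world
        iv = ann.intervals["hns_islands"]
        island_seq = "".join(ann.sequence[s:e] for s, e in zip(iv.starts, iv.ends))
        assert at_fraction(island_seq) == pytest.approx(synth_config.island_at, abs=0.02)

    def test_essential_genes_avoid_islands(self, synth_world):
        ann, _ = synth_world
        isl = ann.intervals["hns_islands"]
        for s, e in zip(ann.intervals["essential"].starts, ann.intervals["essential"].ends):
            assert all(e <= a or s >= b for a, b in zip(isl.starts, isl.ends))

    def test_infeasible_placement_rejected(self):
        with pytest.raises(ValidationError):
            make_genome(SynthConfig(length_bp=50_000, at_island_count=50,
                                    at_island_mean_bp=2000))


class TestSampleInsertions:
    def test_deterministic_and_right_count(self, synth_config):
        ann = make_genome(synth_config)
        a = sample_insertions(ann, synth_config, seed=9)
        b = sample_insertions(ann, synth_config, seed=9)
        assert len(a) == synth_config.n_insertions
        assert np.array_equal(a.positions, b.positions)

    def test_unbiased_config_gives_uniform_positions(self):
        cfg = SynthConfig(length_bp=100_000, at_island_count=5, essential_count=5,
                          n_insertions=50_000, alpha=0.0, at_boost=0.0,
                          essential_survival=1.0, seed=4)
        ann = make_genome(cfg)
        ins = sample_insertions(ann, cfg)
        counts, _ = np.histogram(ins.positions, bins=20, range=(0, cfg.length_bp))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_zero_survival_empties_essential_genes(self):
        cfg = SynthConfig(length_bp=100_000, at_island_count=5, essential_count=10,
                          n_insertions=5000, essential_survival=0.0, seed=5)
        ann = make_genome(cfg)
        ins = sample_insertions(ann, cfg)
        ess = ann.intervals["essential"]
        segs = _merged_segments(ess, ann.spec, 0)
        assert not _inside(ins.positions.astype(float), *segs).any()

    def test_alpha_three_recovered_by_exponent_fit(self):
        cfg = SynthConfig(length_bp=500_000, n_insertions=100_000, alpha=3.0,
                          at_boost=0.0, essential_survival=1.0, seed=6)
        ann = make_genome(cfg)
        ins = sample_insertions(ann, cfg)
        prof = sliding_coverage(ins.as_sites(), ann.spec, 3000, 3000)
        fit = fit_dosage_exponent(prof, dosage_prediction_for(prof, cfg.dosage))
        assert fit.alpha == pytest.approx(3.0, abs=0.2)


class TestPhenotypes:
    def test_classes_follow_position_rules(self, synth_world, synth_config):
        ann, ins = synth_world
        clones = assign_clone_phenotypes(ins, ann, synth_config)
        rrn_segs = _merged_segments(ann.intervals["rrn"], ann.spec, 0)
        near_islands = _merged_segments(ann.intervals["hns_islands"], ann.spec,
                                        synth_config.hns_proximity_bp)
        for clone in clones[:500]:
            for pos, cls in zip(clone.positions, clone.site_classes):
                in_rrn = bool(_inside(np.array([float(pos)]), *rrn_segs)[0])
                near = bool(_inside(np.array([float(pos)]), *near_islands)[0])
                if cls == "rrn_switching":
                    assert in_rrn
                elif cls == "silenced":
                    assert near
                else:
                    assert not near

    def test_multi_insertion_fraction_zero(self, synth_world):
        ann, ins = synth_world
        cfg = SynthConfig(length_bp=200_000, at_island_count=10, essential_count=15,
                          n_insertions=4000, multi_insertion_fraction=0.0, seed=11)
        clones = assign_clone_phenotypes(ins, ann, cfg)
        assert all(c.copy_number == 1 for c in clones)

    def test_opposite_orientation_required_for_switching(self, synth_world, synth_config):
        ann, ins = synth_world
        cfg = SynthConfig(**{**synth_config.__dict__, "opposite_orientation_prob": 0.0})
        clones = assign_clone_phenotypes(ins, ann, cfg)
        assert all(c.clone_class != "rrn_switching" for c in clones)


class TestCellExpression:
    def test_zero_extrinsic_cv_gives_constant_cells(self, synth_world, synth_config):
        ann, ins = synth_world
        cfg = SynthConfig(**{**synth_config.__dict__, "cv_ext": 0.0,
                             "multi_insertion_fraction": 0.0})
        clone = next(c for c in assign_clone_phenotypes(ins, ann, cfg)
                     if c.clone_class == "normal")
        expr = sample_cell_expression(clone, 100, "LB", cfg, seed=1)
        assert np.allclose(expr.cells, expr.cells[0])

    def test_telegraph_occupancy_half_when_rates_equal(self, synth_world, synth_config):
        ann, ins = synth_world
        sw = SwitchParams(k_on=0.02, k_off=0.02, level_on=400.0, level_off=0.0)
        cfg = SynthConfig(**{**synth_config.__dict__, "switch": sw, "cv_ext": 0.0})
        clones = assign_clone_phenotypes(ins, ann, cfg)
        clone = next(c for c in clones if c.clone_class == "rrn_switching")
        expr = sample_cell_expression(clone, 10_000, "LB", cfg, seed=2)
        frac_on = np.mean(expr.cells > 200)
        assert frac_on == pytest.approx(0.5, abs=3 * 0.005)  # 3 binomial sigma

    def test_extrinsic_regime_sd_proportional_to_mean(self, synth_world, synth_config):
        ann, ins = synth_world
        clones = [c for c in assign_clone_phenotypes(ins, ann, synth_config)
                  if c.clone_class == "normal" and c.copy_number == 1][:30]
        ss = [clone_stats(sample_cell_expression(c, 2000, "LB", synth_config, seed=i).cells,
                          c.clone_id) for i, c in enumerate(clones)]
        cvs = np.array([s.sd / s.mean for s in ss])
        assert np.all(np.abs(cvs - synth_config.cv_ext) < 0.05)


class TestSortPopulation:
    @staticmethod
    def _two_clone_pop():
        from insertion_fate.core import CloneExpression
        low = CloneExpression("low", [1], "LB", 2.0, np.full(100, 10.0))
        high = CloneExpression("high", [2], "LB", 2.0, np.full(100, 100.0))
        return [low, high]

    def test_gate_covering_everything_keeps_frequencies(self):
        clones = self._two_clone_pop()
        out = sort_population(clones, [0.25, 0.75], (0.0, np.inf))
        np.testing.assert_allclose(out, [0.25, 0.75])

    def test_exclusive_gate_zeroes_a_clone(self):
        clones = self._two_clone_pop()
        out = sort_population(clones, [0.5, 0.5], (50.0, np.inf))
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1.0)

    def test_empty_gate_rejected(self):
        clones = self._two_clone_pop()
        with pytest.raises(ValidationError):
            sort_population(clones, [0.5, 0.5], (1000.0, 2000.0))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_low_gate_enriches_low_expression_classes(self, synth_world, synth_config, seed):
        ann, ins = synth_world
        clones = assign_clone_phenotypes(ins, ann, synth_config)[:300]
        exprs = [sample_cell_expression(c, 200, "LB", synth_config, seed=seed * 1000 + i)
                 for i, c in enumerate(clones)]
        pooled = np.concatenate([e.cells for e in exprs])
        gate = (0.0, float(np.quantile(pooled, 0.3)))
        f0 = np.ones(len(clones)) / len(clones)
        f1 = sort_population(exprs, f0, gate)
        lowmask = np.array([c.clone_class != "normal" for c in clones])
        assert f1[lowmask].sum() > f0[lowmask].sum()


class TestMicrocolony:
    def test_tree_arithmetic(self, synth_world, synth_config):
        ann, ins = synth_world
        clone = assign_clone_phenotypes(ins, ann, synth_config)[0]
        tree = simulate_microcolony(clone, synth_config, generations=3, seed=1)
        assert len(tree.leaves()) == 8
        assert tree.n_divisions() == 7

    def test_quiet_clone_has_zero_divergence(self, synth_world, synth_config):
        ann, ins = synth_world
        cfg = SynthConfig(**{**synth_config.__dict__, "lineage_cv": 0.0, "meas_cv": 0.0})
        clone = next(c for c in assign_clone_phenotypes(ins, ann, cfg)
                     if c.clone_class == "normal")
        tree = simulate_microcolony(clone, cfg, seed=2)
        assert sister_divergence(tree).colony_divergence == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_given_seed(self, synth_world, synth_config):
        ann, ins = synth_world
        clone = assign_clone_phenotypes(ins, ann, synth_config)[0]
        t1 = simulate_microcolony(clone, synth_config, seed=3)
        t2 = simulate_microcolony(clone, synth_config, seed=3)
        for cid in t1.series:
            np.testing.assert_array_equal(t1.series[cid][1], t2.series[cid][1])
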