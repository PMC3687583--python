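"""Cross simulator: map generation, meiosis, inbreeding, trait model."""

import numpy as np
import pytest

from bsamap import (EpistasisMask, SegregantGenome, TraitModel, assign_phenotype,
                    default_trait_model, inbreed, junction_count, origins_matrix,
                    simulate_f1_population, simulate_meiosis, simulate_parental_genomes,
                    subset_trait_model)
from bsamap.sim_cross import ORIGIN_INFERIOR, ORIGIN_SUPERIOR


class TestParentalMap:
    def test_degenerate_single_marker(self):
        m = simulate_parental_genomes(1, 1, 10 ** 6, 0.5, seed=0)
        assert m.n_markers == 1
        assert 1 <= m.pos[0] <= 10 ** 6
        assert m.superior_allele[0] != m.inferior_allele[0]

    def test_study_scale_marker_count(self):
        m = simulate_parental_genomes(16, 350, 750_000, 2.7, seed=3)
        assert m.n_markers == 5_600
        for _, sl in m.chromosome_slices().items():
            assert np.all(np.diff(m.pos[sl]) > 0)
        assert np.all(m.superior_allele != m.inferior_allele)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_parental_genomes(3, 25, 100_000, 1.0, seed=9)
        b = simulate_parental_genomes(3, 25, 100_000, 1.0, seed=9)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.superior_allele, b.superior_allele)

    @pytest.mark.parametrize("kwargs", [
        dict(n_chromosomes=0, markers_per_chromosome=10),
        dict(n_chromosomes=2, markers_per_chromosome=0),
        dict(n_chromosomes=2, markers_per_chromosome=10, chrom_lengths=-5),
        dict(n_chromosomes=2, markers_per_chromosome=10, map_lengths=-1.0),
    ])
    def test_rejects_nonpositive_sizes(self, kwargs):
        with pytest.raises(ValueError):
            simulate_parental_genomes(**kwargs)

    def test_subset_is_a_valid_map(self, small_map):
        sub = small_map.subset([0, 5, 17, 80])
        assert sub.n_markers == 4
        # only chromosomes that retain markers are kept, with their lengths
        assert np.array_equal(sub.chromosomes, np.unique(small_map.chrom[[0, 5, 17, 80]]))
        assert all(sub.length_of(int(c)) == small_map.length_of(int(c))
                   for c in sub.chromosomes)


class TestMeiosis:
    def test_zero_map_length_gives_intact_chromosomes(self):
        m = simulate_parental_genomes(3, 30, 200_000, 0.0, seed=1)
        for i in range(10):
            g = simulate_meiosis(m, seed=i)
            assert junction_count(g, m) == 0

    def test_junction_rate_matches_map_length(self):
        # Haldane model: expected junctions per chromosome = map length (M)
        m = simulate_parental_genomes(1, 200, 500_000, 0.8, seed=2)
        pop = simulate_f1_population(m, 10_000, seed=5)
        mat = origins_matrix(pop)
        junctions = (mat[:, :-1] != mat[:, 1:]).sum(axis=1)
        se = junctions.std(ddof=1) / np.sqrt(len(junctions))
        assert abs(junctions.mean() - 0.8) < 3 * se

    def test_fair_segregation_at_every_marker(self):
        m = simulate_parental_genomes(1, 20, 300_000, 0.8, seed=4)
        pop = simulate_f1_population(m, 10_000, seed=6)
        freq = (origins_matrix(pop) == ORIGIN_SUPERIOR).mean(axis=0)
        se = 0.5 / np.sqrt(10_000)
        assert np.all(np.abs(freq - 0.5) < 3 * se)

    def test_linkage_decays_with_distance_and_vanishes_across_chromosomes(self):
        m = simulate_parental_genomes(2, 50, 400_000, 1.5, seed=8)
        mat = origins_matrix(simulate_f1_population(m, 10_000, seed=9)).astype(float)
        sl = m.chromosome_slices()
        c1 = sl[1]
        r_near = np.corrcoef(mat[:, c1.start], mat[:, c1.start + 1])[0, 1]
        r_far = np.corrcoef(mat[:, c1.start], mat[:, c1.stop - 1])[0, 1]
        assert r_near > r_far
        r_trans = np.corrcoef(mat[:, c1.start], mat[:, sl[2].start])[0, 1]
        assert abs(r_trans) < 3 / np.sqrt(10_000)

    def test_meiosis_of_identical_parents_reproduces_them(self, small_map):
        hap = np.ones(small_map.n_markers, dtype=np.uint8)
        child = simulate_meiosis(small_map, seed=3, parent_a=hap, parent_b=hap)
        assert np.array_equal(child.origins, hap)


class TestInbreeding:
    def test_zero_rounds_is_identity(self, small_map):
        pop = simulate_f1_population(small_map, 6, seed=1)
        out = inbreed(pop, 0, small_map, seed=2)
        assert [s.strain_id for s in out] == [s.strain_id for s in pop]

    def test_four_rounds_reach_generation_f5(self, small_map):
        pop = simulate_f1_population(small_map, 10, seed=1)
        out = inbreed(pop, 4, small_map, seed=2)
        assert len(out) == 10
        assert all(s.generation == "F5" for s in out)

    def test_recombination_accumulates_with_rounds(self, small_map):
        pop = simulate_f1_population(small_map, 2_000, seed=3)
        f5 = inbreed(pop, 4, small_map, seed=4)
        j1 = np.mean([junction_count(s, small_map) for s in pop])
        j5 = np.mean([junction_count(s, small_map) for s in f5])
        assert j5 > j1

    def test_rejects_population_below_two(self, small_map):
        pop = simulate_f1_population(small_map, 1, seed=1)
        with pytest.raises(ValueError):
            inbreed(pop, 1, small_map, seed=2)


class TestTraitModel:
    def _model(self, **kw):
        base = dict(causal_loci=(0, 1, 2, 3), effects=(15.0, 8.0, 6.0, 5.0),
                    masks={0: EpistasisMask(suppressors=(1, 2), rule="any")},
                    sigma_glycerol=0.0, sigma_ethanol=0.0)
        base.update(kw)
        return TraitModel(**base)

    def _segregant(self, origins):
        return SegregantGenome(origins=np.array(origins, dtype=np.uint8))

    def test_all_superior_genotype_sits_at_reference(self):
        g = self._segregant([ORIGIN_SUPERIOR] * 4)
        assert assign_phenotype(g, self._model(), seed=0) == (100.0, 100.0)

    def test_all_inferior_genotype_reproduces_parent_scale(self):
        # unmasked sum 15+8+6+5 = 34 points; coupling 0.041 -> ethanol 98.6
        model = self._model(masks={})
        g = self._segregant([ORIGIN_INFERIOR] * 4)
        gly, eth = assign_phenotype(g, model, seed=0)
        assert gly == pytest.approx(134.0)
        assert eth == pytest.approx(100 - 0.041 * 34, abs=1e-9)

    def test_masked_locus_effect_vanishes_in_suppressive_background(self):
        g = self._segregant([ORIGIN_INFERIOR, ORIGIN_SUPERIOR, ORIGIN_SUPERIOR,
                             ORIGIN_SUPERIOR])
        gly, eth = assign_phenotype(g, self._model(), seed=0)
        assert (gly, eth) == (100.0, 100.0)

    def test_all_rule_requires_every_suppressor(self):
        model = self._model(masks={0: EpistasisMask(suppressors=(1, 2), rule="all")})
        mixed = self._segregant([ORIGIN_INFERIOR, ORIGIN_SUPERIOR, ORIGIN_INFERIOR,
                                 ORIGIN_SUPERIOR])
        gly, _ = assign_phenotype(mixed, model, seed=0)
        assert gly == pytest.approx(100 + 15 + 6)   # mask not met, minor 2 inferior

    def test_replicate_mean_shrinks_noise(self):
        model = self._model(sigma_glycerol=8.0)
        g = self._segregant([ORIGIN_SUPERIOR] * 4)
        rng = np.random.default_rng(0)
        singles = np.array([assign_phenotype(g, model, rng)[0] for _ in range(500)])
        triples = np.array([assign_phenotype(g, model, rng, replicates=3)[0]
                            for _ in range(500)])
        assert triples.std() < singles.std()

    @pytest.mark.parametrize("kw", [
        dict(effects=(-1.0, 8.0, 6.0, 5.0)),
        dict(sigma_glycerol=-0.1),
        dict(masks={9: EpistasisMask(suppressors=(1,))}),
        dict(masks={0: EpistasisMask(suppressors=(7,))}),
    ])
    def test_invalid_models_rejected(self, kw):
        with pytest.raises(ValueError):
            self._model(**kw)

    def test_epistasis_recovered_by_stratified_regression(self, small_map):
        # effect ~ delta in the permissive background, ~ 0 in the suppressive one
        model = TraitModel(causal_loci=(0, 50, 90), effects=(10.0, 5.0, 5.0),
                           masks={0: EpistasisMask(suppressors=(50, 90), rule="any")},
                           sigma_glycerol=2.0, sigma_ethanol=0.1)
        pop = simulate_f1_population(small_map, 4_000, seed=10)
        mat = origins_matrix(pop)
        rng = np.random.default_rng(11)
        g = model.genetic_values(mat)
        gly = 100 + g + rng.normal(0, 2.0, len(g))
        x = (mat[:, 0] == ORIGIN_INFERIOR).astype(float)
        permissive = (mat[:, 50] == ORIGIN_INFERIOR) & (mat[:, 90] == ORIGIN_INFERIOR)
        for stratum, expected in ((permissive, 10.0), (~permissive, 0.0)):
            xx, yy = x[stratum], gly[stratum]
            slope = np.cov(xx, yy)[0, 1] / np.var(xx)
            n1, n0 = int(xx.sum()), int((1 - xx).sum())
            se = yy.std(ddof=1) * np.sqrt(1 / n1 + 1 / n0)
            assert abs(slope - expected) < 3 * se

    def test_default_model_covers_genome(self, yeast_map, yeast_model):
        assert len(yeast_model.causal_loci) == 4
        assert sorted(yeast_model.effects, reverse=True) == [15.0, 8.0, 6.0, 5.0]
        assert len(yeast_model.background_loci) == 36
        chroms = {int(yeast_map.chrom[l]) for l in yeast_model.causal_loci}
        assert len(chroms) == 4

    def test_subset_trait_model_remaps_indices(self, yeast_model):
        loci = sorted(set(yeast_model.causal_loci) | set(yeast_model.background_loci))
        sub = subset_trait_model(yeast_model, loci)
        assert max(sub.causal_loci + sub.background_loci) < len(loci)
        assert sub.effects == yeast_model.effects
        with pytest.raises(ValueError):
            subset_trait_model(yeast_model, loci[:-1])
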