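"""The synthetic-genome generator and its truth-table guarantees."""

import math

import numpy as np
import pytest

import ltrtrace as lt


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        cfg = lt.SimulationConfig(seed=13, genome_length=120_000, n_intact=4,
                                  n_solo=1, n_truncated=2)
        r1 = lt.simulate_genome(cfg)
        r2 = lt.simulate_genome(cfg)
        assert r1.genome == r2.genome
        assert r1.truth == r2.truth

    def test_truth_slices_reproduce_planted_sequences(self, zero_age_sim):
        g = zero_age_sim.genome
        for t in zero_age_sim.truth:
            assert g[t.chrom][t.start - 1 : t.end] == t.planted_seq

    def test_tsd_copies_flank_every_insertion(self, zero_age_sim):
        g = zero_age_sim.genome
        for t in zero_age_sim.truth:
            s0, e0 = t.start - 1, t.end
            assert g[t.chrom][s0 - 5 : s0] == t.tsd_seq
            assert g[t.chrom][e0 : e0 + 5] == t.tsd_seq

    def test_category_counts_match_config(self, zero_age_sim):
        cats = [t.category for t in zero_age_sim.truth]
        assert cats.count("intact_with_tsd") == 8
        assert cats.count("solo_with_tsd") == 2
        assert sum(1 for c in cats if c.startswith("trunc")) == 3

    def test_empty_config_gives_pure_background(self):
        cfg = lt.SimulationConfig(seed=1, genome_length=50_000, n_intact=0,
                                  n_solo=0, n_truncated=0)
        res = lt.simulate_genome(cfg)
        assert res.truth == []
        assert len(res.genome[cfg.chrom_name]) == 50_000

    def test_ltr_pair_divergence_matches_mutation_model(self):
        """At age 1 My the two LTRs of an element should differ at a per-site
        rate of ~2(1-exp(-r t)) (pooled over elements, within 3 SE)."""
        cfg = lt.SimulationConfig(seed=4, genome_length=500_000, n_intact=30,
                                  n_solo=0, n_truncated=0,
                                  age_distribution=("point", 1_000_000.0))
        res = lt.simulate_genome(cfg)
        g = res.genome[cfg.chrom_name]
        mism = sites = 0
        for t in res.truth:
            l5 = g[t.ltr5[0] - 1 : t.ltr5[1]]
            l3 = g[t.ltr3[0] - 1 : t.ltr3[1]]
            mism += sum(1 for a, b in zip(l5, l3) if a != b)
            sites += len(l5)
        p1 = 1 - math.exp(-cfg.r * 1e6)
        # per-site probability the two LTRs differ: one copy hit (and not the
        # other), or both hit landing on different bases (2/3 of double hits)
        expected = 2 * p1 * (1 - p1) + (2 / 3) * p1 * p1
        se = math.sqrt(expected * (1 - expected) / sites)
        assert abs(mism / sites - expected) <= 3 * se

    def test_genome_too_small_rejected(self):
        cfg = lt.SimulationConfig(seed=1, genome_length=10_000, n_intact=50,
                                  n_solo=0, n_truncated=0)
        with pytest.raises(ValueError):
            lt.simulate_genome(cfg)

    def test_weighted_site_regions_bias_placement(self):
        cfg = lt.SimulationConfig(
            seed=5, genome_length=1_000_000, n_intact=40, n_solo=0, n_truncated=0,
            site_regions=[(1_000, 200_000, 10.0), (200_000, 999_000, 0.1)],
        )
        res = lt.simulate_genome(cfg)
        # site_regions are background coordinates; planted elements shift final
        # coordinates right by up to the total inserted length (~190 kb here)
        limit = 200_000 + 40 * (4700 + 10)
        in_first = sum(1 for t in res.truth if t.start < limit)
        assert in_first >= 30


class TestSimulateSister:
    def test_identical_when_all_shared_and_no_divergence(self, identical_sister,
                                                         zero_age_sim):
        assert identical_sister.genome_a == identical_sister.genome_b
        assert all(t.shared for t in identical_sister.truth)

    def test_b_coordinates_point_at_the_insertion(self, identical_sister):
        gb = identical_sister.genome_b
        for t in identical_sister.truth:
            assert gb[t.b_chrom][t.b_start - 1 : t.b_end] == t.planted_seq

    def test_excision_leaves_single_tsd_copy(self, zero_age_sim):
        sis = lt.simulate_sister(zero_age_sim.genome, zero_age_sim.truth,
                                 split_time=0.0, shared_fraction=0.0, seed=2)
        assert all(t.shared is False for t in sis.truth)
        gb = sis.genome_b[zero_age_sim.config.chrom_name]
        ga = zero_age_sim.genome[zero_age_sim.config.chrom_name]
        removed = sum(len(t.planted_seq) + 5 for t in sis.truth)
        assert len(gb) == len(ga) - removed
        # each emptied locus retains exactly one TSD copy between its flanks
        offset = 0
        for t in sorted(sis.truth, key=lambda x: x.start):
            s0 = t.start - 1 - offset
            assert gb[s0 - 5 : s0] == t.tsd_seq
            assert gb[s0 : s0 + 5] != t.tsd_seq or t.planted_seq[:5] == t.tsd_seq
            offset += len(t.planted_seq) + 5

    def test_orthologous_divergence_near_2rt(self, zero_age_sim):
        T = 500_000.0
        sis = lt.simulate_sister(zero_age_sim.genome, zero_age_sim.truth,
                                 split_time=T, shared_fraction=1.0, seed=3)
        ga = sis.genome_a[zero_age_sim.config.chrom_name]
        gb = sis.genome_b[zero_age_sim.config.chrom_name]
        assert len(ga) == len(gb)
        mism = sum(1 for a, b in zip(ga[:200_000], gb[:200_000]) if a != b)
        p1 = 1 - math.exp(-1.3e-8 * T)
        expected = 2 * p1 * (1 - p1) + (2 / 3) * p1 * p1
        se = math.sqrt(expected * (1 - expected) / 200_000)
        assert abs(mism / 200_000 - expected) <= 4 * se

    def test_bad_fraction_rejected(self, zero_age_sim):
        with pytest.raises(ValueError):
            lt.simulate_sister(zero_age_sim.genome, zero_age_sim.truth, 0.0, 1.5, 1)


class TestRetroLineage:
    def test_three_prime_mutation_propagates_to_all_descendants(self):
        pop = lt.simulate_retro_lineage(lt.RetroLineageConfig(seed=0))
        assert lt.descendant_termini_fraction(pop, "TA..CA") == 1.0
        founder = pop[0]
        assert founder.ltr5[:2] == "TG" and founder.ltr3[:2] == "TA"

    def test_five_prime_mutation_reverts_in_daughters(self):
        pop = lt.simulate_retro_lineage(
            lt.RetroLineageConfig(seed=0, mutated_ltr="five_prime")
        )
        assert lt.descendant_termini_fraction(pop, "TG..CA") == 1.0
        assert lt.descendant_termini_fraction(pop, "TA..CA") == 0.0

    def test_zero_generations_returns_only_founder(self):
        pop = lt.simulate_retro_lineage(lt.RetroLineageConfig(seed=1, generations=0))
        assert len(pop) == 1
        with pytest.raises(ValueError):
            lt.descendant_termini_fraction(pop, "TA..CA")

    def test_genealogy_is_consistent(self):
        pop = lt.simulate_retro_lineage(lt.RetroLineageConfig(seed=2, generations=2,
                                                              copies_per_generation=3))
        ids = {e.element_id for e in pop}
        for e in pop:
            if e.generation > 0:
                assert e.parent_id in ids

    def test_mutation_outside_u3_rejected(self):
        with pytest.raises(ValueError):
            lt.RetroLineageConfig(mutation_position=150, u3_end_offset=120)


class TestMutationModel:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        assert lt.mutate_sequence("ACGT" * 100, 0.0, rng) == "ACGT" * 100

    def test_substitutions_only_no_indels(self):
        rng = np.random.default_rng(1)
        s = "ACGT" * 250
        m = lt.mutate_sequence(s, 0.2, rng)
        assert len(m) == len(s)
        assert m != s
        assert set(m) <= set("ACGT")
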