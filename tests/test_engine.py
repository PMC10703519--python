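import numpy as np
import pytest
from scipy import stats as sps

import wfscape as w
from wfscape.errors import ConfigError, DegeneratePopulationError, InvalidParameterError

from conftest import flat_landscape


class TestPairing:
    def test_two_individuals_form_the_single_pair(self, rng):
        pop = w.Population(1, np.array([0, 1]))
        pairs = w.pair_individuals(pop, rng)
        assert sorted(pairs.ravel().tolist()) == [0, 1]

    def test_every_matching_equally_likely(self, rng):
        # N=4 has exactly 3 perfect matchings
        pop = w.Population(1, np.zeros(4, dtype=np.int64))
        counts = {}
        n = 10_000
        for _ in range(n):
            pairs = w.pair_individuals(pop, rng)
            key = frozenset(frozenset(p) for p in pairs.tolist())
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 3 * se

    def test_output_partitions_population(self, rng):
        pop = w.Population(1, np.zeros(1000, dtype=np.int64))
        pairs = w.pair_individuals(pop, rng)
        assert sorted(pairs.ravel().tolist()) == list(range(1000))


class TestRecombination:
    def test_zero_rates_return_parents(self, rng):
        rmap = w.RecombinationMap.uniform(4, 0.0)
        for _ in range(20):
            g1, g2 = w.recombine_pair(0b1010, 0b0101, rmap, rng)
            assert {g1, g2} == {0b1010, 0b0101}

    def test_free_recombination_uniform_over_gametes(self, rng):
        # L=2, r=0.5, parents 00 and 11: first gamete uniform over 4 genotypes
        rmap = w.RecombinationMap.uniform(2, 0.5)
        n = 10_000
        first = [w.recombine_pair(0b00, 0b11, rmap, rng)[0] for _ in range(n)]
        observed = np.bincount(first, minlength=4)
        _, p = sps.chisquare(observed)
        assert p > 0.001

    def test_complementarity_preserves_allele_counts(self, rng):
        rmap = w.RecombinationMap(rng.random(7) / 2)
        for _ in range(50):
            g1, g2 = int(rng.integers(256)), int(rng.integers(256))
            a, b = w.recombine_pair(g1, g2, rmap, rng)
            for locus in range(8):
                bit = 1 << locus
                assert bool(a & bit) + bool(b & bit) == bool(g1 & bit) + bool(g2 & bit)

    def test_rates_outside_half_rejected(self):
        with pytest.raises(InvalidParameterError):
            w.RecombinationMap([0.6])
        with pytest.raises(InvalidParameterError):
            w.RecombinationMap([-0.1])

    def test_map_from_file(self, tmp_path):
        path = tmp_path / "map.txt"
        path.write_text("0.1\n0.2\n0.3\n")
        rmap = w.RecombinationMap.from_file(path, L=4)
        np.testing.assert_allclose(rmap.rates, [0.1, 0.2, 0.3])
        with pytest.raises(ConfigError, match="expected L-1 = 4"):
            w.RecombinationMap.from_file(path, L=5)


class TestMutation:
    def test_zero_rate_leaves_gametes_unchanged(self, rng):
        gametes = rng.integers(0, 16, size=100)
        np.testing.assert_array_equal(w.mutate_pool(gametes, 0.0, 4, rng), gametes)

    def test_flip_count_matches_rate(self, rng):
        # 1e5 gametes x 10 loci at mu=1e-5: expect 10 flips (Poisson sd ~ sqrt(10))
        gametes = np.zeros(100_000, dtype=np.int64)
        mutated = w.mutate_pool(gametes, 1e-5, 10, rng)
        bits = (mutated[:, None] >> np.arange(10)) & 1
        flips = int(bits.sum())
        assert abs(flips - 10) < 3 * np.sqrt(10)

    def test_flip_distribution_is_binomial(self, rng):
        # all-zero gametes, mu=0.5, L=10: flips per gamete ~ Binomial(10, 1/2)
        mutated = w.mutate_pool(np.zeros(10_000, dtype=np.int64), 0.5, 10, rng)
        flips = np.array([bin(g).count("1") for g in mutated])
        observed = np.bincount(flips, minlength=11)
        expected = sps.binom.pmf(np.arange(11), 10, 0.5) * flips.size
        _, p = sps.chisquare(observed, expected)
        assert p > 0.001

    def test_bidirectional(self, rng):
        ones = (1 << 10) - 1
        mutated = w.mutate_pool(np.full(10_000, ones, dtype=np.int64), 0.5, 10, rng)
        assert mutated.min() < ones  # 1 -> 0 flips happen too


class TestSelection:
    def test_flat_landscape_uniform_multinomial(self, rng):
        ls = flat_landscape(2)
        pool = np.repeat(np.arange(4), 2500)
        offspring = w.select_offspring(pool, ls, 10_000, rng)
        observed = np.bincount(offspring.genotypes, minlength=4)
        _, p = sps.chisquare(observed)
        assert p > 0.001

    def test_offspring_proportional_to_fitness(self):
        # pool half g=0 (w=1) and half g=1 (w=3): expect 75% of offspring g=1
        ls = w.landscape_from_table([("0", 1.0), ("1", 3.0)])
        pool = np.repeat([0, 1], 500)
        fractions = [
            w.select_offspring(pool, ls, 1000, np.random.default_rng(8000 + i))
            .genotypes.mean()
            for i in range(20)
        ]
        se = np.sqrt(0.75 * 0.25 / (20 * 1000))
        assert abs(np.mean(fractions) - 0.75) < 3 * se

    def test_zero_fitness_gamete_never_sampled(self, rng):
        ls = w.landscape_from_table([("0", 1.0), ("1", 0.0)])
        pool = np.repeat([0, 1], 500)
        offspring = w.select_offspring(pool, ls, 1000, rng)
        assert not offspring.genotypes.any()

    def test_all_zero_weights_is_degenerate(self, rng):
        ls = w.landscape_from_table([("0", 0.0), ("1", 1.0)])
        with pytest.raises(DegeneratePopulationError):
            w.select_offspring(np.zeros(10, dtype=np.int64), ls, 10, rng)


class TestStepGeneration:
    def test_monomorphic_population_is_absorbing(self, rng):
        ls = w.gen_hoc(4, rng=1)
        pop = w.Population(4, np.full(50, 11, dtype=np.int64))
        nxt = w.step_generation(pop, ls, w.RecombinationMap.uniform(4, 0.3), w.EngineConfig(), rng)
        np.testing.assert_array_equal(nxt.genotypes, pop.genotypes)

    def test_population_size_preserved(self, rng):
        ls = flat_landscape(3)
        rmap = w.RecombinationMap.uniform(3, 0.1)
        pop = w.init_equal(40, 3, 0.5, rng)
        for _ in range(100):
            pop = w.step_generation(pop, ls, rmap, w.EngineConfig(), rng)
            assert pop.N == 40

    def test_map_length_mismatch_rejected(self, rng):
        pop = w.init_equal(10, 3, 0.5, rng)
        with pytest.raises(InvalidParameterError):
            w.step_generation(pop, flat_landscape(3), w.RecombinationMap.uniform(4, 0.1),
                              w.EngineConfig(), rng)


class TestMonomorphism:
    def test_identical_individuals(self):
        assert w.is_monomorphic(w.Population(3, np.full(10, 5, dtype=np.int64)))

    def test_single_deviant_individual(self):
        genotypes = np.full(10, 5, dtype=np.int64)
        genotypes[3] ^= 1  # one individual differs at one locus
        assert not w.is_monomorphic(w.Population(3, genotypes))

    def test_matches_bitwise_oracle(self, rng):
        for _ in range(50):
            pop = w.Population(4, rng.integers(0, 16, size=20, dtype=np.int64))
            g = pop.genotypes
            oracle = int(np.bitwise_and.reduce(g)) == int(np.bitwise_or.reduce(g))
            assert w.is_monomorphic(pop) == oracle


class TestEngineConfig:
    def test_mutation_requires_stopping_generation(self):
        with pytest.raises(ConfigError):
            w.EngineConfig(mutation_rate=1e-5)

    @pytest.mark.parametrize("mu", [-0.1, 1.0])
    def test_mutation_rate_domain(self, mu):
        with pytest.raises(InvalidParameterError):
            w.EngineConfig(mutation_rate=mu, max_generations=100)


class TestRun:
    def test_neutral_run_terminates_monomorphic(self, rng):
        res = w.run_replicate(
            w.init_equal(60, 4, 0.5, rng), flat_landscape(4),
            w.RecombinationMap.uniform(4, 0.1), w.EngineConfig(record_interval=10), rng,
        )
        assert res.summary.total_generations >= 1
        assert w.is_monomorphic(res.final_population)
        assert np.all(res.summary.fixation.times >= 0)  # all loci fixed

    def test_final_generation_always_recorded(self, rng):
        res = w.run_replicate(
            w.init_equal(60, 3, 0.5, rng), flat_landscape(3),
            w.RecombinationMap.uniform(3, 0.1), w.EngineConfig(record_interval=1000), rng,
        )
        gens = [r.generation for r in res.records]
        assert gens[0] == 0
        assert gens[-1] == res.summary.total_generations

    def test_mutation_run_stops_at_max_generations(self, rng):
        cfg = w.EngineConfig(mutation_rate=1e-3, max_generations=25, record_interval=10)
        res = w.run_replicate(
            w.init_equal(60, 3, 0.5, rng), flat_landscape(3),
            w.RecombinationMap.uniform(3, 0.1), cfg, rng,
        )
        assert res.summary.total_generations == 25
        assert [r.generation for r in res.records] == [0, 10, 20, 25]

    def test_exact_fixation_times_match_interval_one_records(self):
        kwargs = dict(
            pop=w.init_equal(40, 3, 0.5, np.random.default_rng(77)),
            landscape=w.gen_hoc(3, rng=4),
            rmap=w.RecombinationMap.uniform(3, 0.2),
        )
        coarse = w.run_replicate(
            config=w.EngineConfig(record_interval=7, exact_fixation_times=True),
            rng=np.random.default_rng(78), **kwargs,
        )
        fine = w.run_replicate(
            config=w.EngineConfig(record_interval=1),
            rng=np.random.default_rng(78), **kwargs,
        )
        np.testing.assert_array_equal(coarse.summary.fixation.times, fine.summary.fixation.times)
        np.testing.assert_array_equal(coarse.summary.fixation.alleles, fine.summary.fixation.alleles)
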