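"""Genetic operators, fitness evaluation and the evolution loop."""

import numpy as np
import pytest

from edmol.chem_core import Fingerprint, canonicalize, encode_ecfp
from edmol.decoder import NNDecoderLibrary
from edmol.ga_engine import (
    FitnessSpec,
    GAConfig,
    Individual,
    WORST_FITNESS,
    crossover_uniform,
    evaluate_population,
    evolve,
    init_population,
    library_decoder_fn,
    mutate_gaussian,
    select_tournament,
)
from edmol.predictor import SurrogateOracle


def _rand_fp(rng, n=5000, density=0.02):
    return Fingerprint((rng.random(n) < density).astype(float))


class TestMutateGaussian:
    def test_sigma_zero_is_identity(self, rng):
        fp = _rand_fp(rng)
        out = mutate_gaussian(fp, 0.0, 1.0, rng)
        assert np.array_equal(out.values, fp.values)

    def test_indpb_zero_is_identity(self, rng):
        fp = _rand_fp(rng)
        out = mutate_gaussian(fp, 0.2, 0.0, rng)
        assert np.array_equal(out.values, fp.values)

    def test_input_not_modified_and_clipped(self, rng):
        fp = _rand_fp(rng)
        orig = fp.values.copy()
        out = mutate_gaussian(fp, 5.0, 1.0, rng)
        assert np.array_equal(fp.values, orig)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_perturbed_fraction_matches_indpb(self, rng):
        fp = Fingerprint(np.full(5000, 0.5))
        out = mutate_gaussian(fp, 0.2, 0.01, rng)
        changed = int((out.values != 0.5).sum())
        # binomial(5000, 0.01): 99% interval approx [32, 69]
        assert 25 <= changed <= 80


class TestCrossoverUniform:
    def test_identical_parents_unchanged(self, rng):
        fp = _rand_fp(rng)
        c1, c2 = crossover_uniform(fp, fp, 0.2, rng)
        assert np.array_equal(c1.values, fp.values)
        assert np.array_equal(c2.values, fp.values)

    @pytest.mark.parametrize("ratio,identity", [(0.0, True), (1.0, False)])
    def test_extreme_mixing_ratios(self, rng, ratio, identity):
        a, b = _rand_fp(rng), _rand_fp(rng)
        c1, c2 = crossover_uniform(a, b, ratio, rng)
        if identity:
            assert np.array_equal(c1.values, a.values)
        else:
            assert np.array_equal(c1.values, b.values)
            assert np.array_equal(c2.values, a.values)

    def test_children_conserve_parent_values_per_position(self, rng):
        a, b = _rand_fp(rng, density=0.5), _rand_fp(rng, density=0.5)
        c1, c2 = crossover_uniform(a, b, 0.2, rng)
        same = (c1.values == a.values) & (c2.values == b.values)
        swapped = (c1.values == b.values) & (c2.values == a.values)
        assert np.all(same | swapped)

    def test_swap_fraction_near_mix_ratio(self, rng):
        a = Fingerprint(np.zeros(5000))
        b = Fingerprint(np.ones(5000))
        c1, _ = crossover_uniform(a, b, 0.2, rng)
        frac = c1.values.mean()
        # binomial(5000, 0.2) 99% interval approx [0.185, 0.215]
        assert 0.17 <= frac <= 0.23

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            crossover_uniform(_rand_fp(rng, 10), _rand_fp(rng, 20), 0.2, rng)


class TestSelectTournament:
    def _pop(self, fits):
        return [Individual(fp=Fingerprint(np.zeros(4)), fitness=f) for f in fits]

    def test_singleton_population(self, rng):
        pop = self._pop([1.0])
        assert all(w is pop[0] for w in select_tournament(pop, 5, 3, rng))

    def test_dominant_individual_wins_when_sampled(self, rng):
        # tournaments sample with replacement: the dominant individual wins
        # whenever it is drawn, so with 2 contestants from {weak, strong} the
        # strong one wins 1 - 0.5^2 = 75% of tournaments
        pop = self._pop([0.0, 10.0])
        winners = select_tournament(pop, 2000, 2, rng)
        frac = np.mean([w.fitness == 10.0 for w in winners])
        assert 0.70 <= frac <= 0.80

    def test_empty_population_raises(self, rng):
        with pytest.raises(ValueError):
            select_tournament([], 1, 3, rng)

    def test_uniform_under_equal_fitness(self, rng):
        from scipy import stats

        pop = self._pop([1.0] * 5)
        winners = select_tournament(pop, 10000, 3, rng)
        counts = np.bincount([pop.index(w) for w in winners], minlength=5)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestInitPopulation:
    def test_population_size_and_seed_inclusion(self, rng):
        seed_fp = _rand_fp(rng)
        cfg = GAConfig(pop_size=20)
        pop = init_population(seed_fp, cfg, rng)
        assert len(pop) == 20
        assert np.array_equal(pop[0].fp.values, seed_fp.values)

    def test_mutation_disabled_gives_clones(self, rng):
        seed_fp = _rand_fp(rng)
        cfg = GAConfig(pop_size=10, init_indpb=0.0)
        pop = init_population(seed_fp, cfg, rng)
        for ind in pop:
            assert np.array_equal(ind.fp.values, seed_fp.values)

    def test_mean_distance_scales_with_init_indpb(self, rng):
        seed_fp = Fingerprint(np.full(5000, 0.5))

        def mean_changed(indpb):
            cfg = GAConfig(pop_size=30, init_indpb=indpb)
            pop = init_population(seed_fp, cfg, rng)
            return np.mean([(ind.fp.values != 0.5).sum() for ind in pop[1:]])

        assert mean_changed(0.10) > mean_changed(0.01) * 5


@pytest.fixture(scope="module")
def nn_decoder(fixture_pairs):
    return library_decoder_fn(NNDecoderLibrary(fixture_pairs[:200]))


class TestEvaluatePopulation:
    def test_fitness_is_oracle_on_reencoded_fingerprint(self, fixture_pairs, nn_decoder, rng):
        oracle = SurrogateOracle(names=("s1",))
        seed = fixture_pairs[0][1]
        pop = [Individual(fp=fixture_pairs[i][0]) for i in range(5, 10)]
        spec = FitnessSpec(objective="maximize_property", property_name="s1")
        evaluate_population(pop, nn_decoder, oracle, seed, spec, GAConfig(), rng)
        t0 = oracle(seed)["s1"]
        for ind in pop:
            expected = (oracle(ind.decoded)["s1"] - t0) / abs(t0)
            assert ind.fitness == pytest.approx(expected)

    def test_undecodable_individual_gets_worst_fitness(self, fixture_pairs, rng):
        seed = fixture_pairs[0][1]
        pop = [Individual(fp=fixture_pairs[1][0])]
        spec = FitnessSpec(objective="maximize_property", property_name="s1")
        evaluate_population(
            pop, lambda fp, rng: None, SurrogateOracle(names=("s1",)), seed, spec,
            GAConfig(), rng,
        )
        assert pop[0].fitness == WORST_FITNESS
        assert pop[0].filter_reasons == ("invalid",)

    def test_reference_duplicates_are_filtered(self, fixture_pairs, nn_decoder, rng):
        seed = fixture_pairs[0][1]
        pop = [Individual(fp=fixture_pairs[3][0])]
        ref = frozenset(m.smiles_canonical for _, m in fixture_pairs[:200])
        spec = FitnessSpec(
            objective="maximize_property", property_name="s1", reference_library=ref
        )
        evaluate_population(
            pop, nn_decoder, SurrogateOracle(names=("s1",)), seed, spec, GAConfig(), rng
        )
        assert pop[0].fitness == WORST_FITNESS
        assert "duplicate" in pop[0].filter_reasons


class BitCountOracle:
    """Fitness oracle: number of set bits in the fingerprint."""

    def __call__(self, fp):
        return {"bits": float(np.count_nonzero(fp.binarized()))}


class TestEvolve:
    def test_best_so_far_monotone_and_final_at_least_initial(self, fixture_pairs):
        decoder = library_decoder_fn(NNDecoderLibrary(fixture_pairs[:100]))
        seed = fixture_pairs[0][1]
        cfg = GAConfig(pop_size=20, max_generations=15, patience=10, rng_seed=5)
        spec = FitnessSpec(objective="maximize_property", property_name="bits")
        result = evolve(seed, decoder, BitCountOracle(), spec, cfg)
        fits = [ind.fitness_value for _, ind in result.best_per_generation]
        assert all(b >= a for a, b in zip(fits, fits[1:]))
        assert result.best_overall.fitness_value >= fits[0]

    def test_constant_oracle_terminates_by_stagnation_after_patience(self, fixture_pairs):
        decoder = library_decoder_fn(NNDecoderLibrary(fixture_pairs[:50]))
        seed = fixture_pairs[0][1]
        cfg = GAConfig(pop_size=10, max_generations=100, patience=7, rng_seed=2)
        spec = FitnessSpec(objective="maximize_property", property_name="c")
        result = evolve(seed, decoder, lambda fp: {"c": 1.0}, spec, cfg)
        assert result.termination_reason == "stagnation"
        # best is set at generation 1; exactly `patience` stagnant generations follow
        assert len(result.best_per_generation) == 1 + cfg.patience

    def test_same_seed_reproduces_run_exactly(self, fixture_pairs):
        decoder = library_decoder_fn(NNDecoderLibrary(fixture_pairs[:100]))
        seed = fixture_pairs[0][1]
        cfg = GAConfig(pop_size=15, max_generations=10, patience=5, rng_seed=33)
        spec = FitnessSpec(objective="maximize_property", property_name="bits")
        a = evolve(seed, decoder, BitCountOracle(), spec, cfg)
        b = evolve(seed, decoder, BitCountOracle(), spec, cfg)
        assert [(g, i.fitness_value) for g, i in a.best_per_generation] == [
            (g, i.fitness_value) for g, i in b.best_per_generation
        ]
        assert a.candidates == b.candidates

    def test_invalid_seed_raises(self, fixture_pairs):
        decoder = library_decoder_fn(NNDecoderLibrary(fixture_pairs[:10]))
        spec = FitnessSpec(objective="maximize_property", property_name="bits")
        with pytest.raises(ValueError):
            evolve(canonicalize("C1CC"), decoder, BitCountOracle(), spec, GAConfig())
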