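import numpy as np
import pandas as pd
import pytest

import evomedia as em
from evomedia.errors import (
    DegeneratePopulationError,
    InfeasibleDesignError,
    ReconciliationError,
    StateError,
    ValidationError,
)
from evomedia.ga import _wheel


def one_gene_space(n_steps=1):
    return em.ParameterSpace(
        (em.ParameterSpec("X", 0.0, 0.0, float(n_steps), n_steps),)
    )


def scored(individuals, fitnesses):
    for ind, f in zip(individuals, fitnesses):
        ind.fitness = f
    return individuals


class TestConfig:
    def test_defaults_match_campaign_design(self):
        cfg = em.GAConfig()
        assert cfg.population_size == 30
        assert cfg.crossover_prob == 0.95
        assert cfg.mutation_rate == 0.02
        assert cfg.selection == "roulette"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"crossover_prob": 1.5},
            {"mutation_rate": -0.1},
            {"population_size": 1},
            {"selection": "tournament"},
            {"fitness_scaling": "sigma"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            em.GAConfig(**kwargs)


class TestInitGeneration:
    def test_thirty_unique_individuals(self, aa_space):
        gen = em.init_generation(aa_space, em.GAConfig(seed=42))
        assert gen.index == 1
        assert len(gen.individuals) == 30
        assert len({ind.key for ind in gen.individuals}) == 30
        ids = [ind.treatment_id for ind in gen.individuals]
        assert len(set(ids)) == 30 and ids[0] == "1-1"

    def test_concentrations_match_decoded_chromosomes(self, aa_space):
        gen = em.init_generation(aa_space, em.GAConfig(seed=7))
        for ind in gen.individuals:
            assert np.array_equal(
                ind.concentrations, aa_space.decode_chromosome(ind.chromosome)
            )

    def test_deterministic_under_seed(self, aa_space):
        a = em.init_generation(aa_space, em.GAConfig(seed=5))
        b = em.init_generation(aa_space, em.GAConfig(seed=5))
        assert [i.key for i in a.individuals] == [i.key for i in b.individuals]

    def test_one_bit_space_exhausts_both_codes(self):
        gen = em.init_generation(one_gene_space(1), em.GAConfig(population_size=2))
        assert {ind.key for ind in gen.individuals} == {"0", "1"}

    def test_space_smaller_than_population_is_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            em.init_generation(one_gene_space(1), em.GAConfig(population_size=4))

    def test_uniform_sampling_of_codes(self):
        # 3-bit gene: each code frequency ~1/8 within 3 binomial SE
        space = one_gene_space(7)
        counts = np.zeros(8)
        for seed in range(5000):
            gen = em.init_generation(space, em.GAConfig(population_size=2, seed=seed))
            for ind in gen.individuals:
                counts[int(ind.key, 2)] += 1
        n = counts.sum()
        p = 1 / 8
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(counts / n - p) < 3 * se)


class TestRouletteSelect:
    def test_equal_fitness_is_symmetric(self, demo_space):
        rng = np.random.default_rng(0)
        inds = scored(
            em.init_generation(demo_space, em.GAConfig(population_size=4)).individuals,
            [1.0] * 4,
        )
        draws = [em.roulette_select(inds, rng).treatment_id for _ in range(20_000)]
        freqs = pd.Series(draws).value_counts(normalize=True)
        se = np.sqrt(0.25 * 0.75 / 20_000)
        assert np.all(np.abs(freqs.to_numpy() - 0.25) < 3 * se)

    def test_three_to_one_odds(self, demo_space):
        rng = np.random.default_rng(1)
        inds = scored(
            em.init_generation(demo_space, em.GAConfig(population_size=2)).individuals,
            [3.0, 1.0],
        )
        n = 100_000
        hits = sum(
            em.roulette_select(inds, rng) is inds[0] for _ in range(n)
        )
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se

    def test_single_positive_fitness_always_wins(self, demo_space):
        rng = np.random.default_rng(2)
        inds = scored(
            em.init_generation(demo_space, em.GAConfig(population_size=4)).individuals,
            [0.0, 0.0, 2.0, 0.0],
        )
        for _ in range(50):
            assert em.roulette_select(inds, rng) is inds[2]

    def test_unset_fitness_is_state_error(self, demo_space):
        inds = em.init_generation(demo_space, em.GAConfig(population_size=3)).individuals
        with pytest.raises(StateError):
            em.roulette_select(inds, np.random.default_rng(0))

    def test_all_zero_fitness_degenerate(self, demo_space):
        inds = scored(
            em.init_generation(demo_space, em.GAConfig(population_size=3)).individuals,
            [0.0, -1.0, 0.0],
        )
        with pytest.raises(DegeneratePopulationError):
            em.roulette_select(inds, np.random.default_rng(0))

    def test_negative_fitness_floored_to_zero(self, demo_space):
        inds = scored(
            em.init_generation(demo_space, em.GAConfig(population_size=3)).individuals,
            [-5.0, 1.0, 1.0],
        )
        p = _wheel(inds, "raw")
        assert p[0] == 0.0 and p[1] == p[2] == 0.5

    def test_windowed_wheel_zeroes_the_minimum(self, demo_space):
        inds = scored(
            em.init_generation(demo_space, em.GAConfig(population_size=3)).individuals,
            [1.0, 1.2, 1.4],
        )
        p = _wheel(inds, "window")
        assert p[0] == 0.0
        assert p[1] == pytest.approx(1 / 3) and p[2] == pytest.approx(2 / 3)

    def test_windowed_wheel_uniform_when_flat(self, demo_space):
        inds = scored(
            em.init_generation(demo_space, em.GAConfig(population_size=4)).individuals,
            [1.3] * 4,
        )
        assert np.allclose(_wheel(inds, "window"), 0.25)


class TestCrossover:
    def test_forced_cut_exchanges_suffixes(self, fake_rng):
        space = one_gene_space(63)  # single 6-bit gene
        a = em.Individual.from_chromosome(np.zeros(6, dtype=np.uint8), space)
        b = em.Individual.from_chromosome(np.ones(6, dtype=np.uint8), space)
        rng = fake_rng(randoms=[0.0], integers=[2])  # event occurs, cut after bit 2
        ca, cb, cut = em.crossover(a, b, em.GAConfig(), rng, space)
        assert cut == 2
        assert ca.key == "001111" and cb.key == "110000"

    def test_probability_zero_copies_parents(self, demo_space):
        rng = np.random.default_rng(0)
        gen = em.init_generation(demo_space, em.GAConfig(population_size=2, seed=1))
        a, b = gen.individuals
        ca, cb, cut = em.crossover(a, b, em.GAConfig(crossover_prob=0.0), rng, demo_space)
        assert cut is None and ca.key == a.key and cb.key == b.key

    def test_length_mismatch_rejected(self, demo_space):
        a = em.Individual.from_chromosome(np.zeros(4, dtype=np.uint8), one_gene_space(15))
        b = em.Individual.from_chromosome(
            np.zeros(demo_space.chromosome_length, dtype=np.uint8), demo_space
        )
        with pytest.raises(ValidationError):
            em.crossover(a, b, em.GAConfig(), np.random.default_rng(0), demo_space)

    def test_event_rate_matches_config(self, demo_space):
        rng = np.random.default_rng(11)
        gen = em.init_generation(demo_space, em.GAConfig(population_size=2, seed=1))
        a, b = gen.individuals
        n = 10_000
        events = sum(
            em.crossover(a, b, em.GAConfig(), rng, demo_space)[2] is not None
            for _ in range(n)
        )
        se = np.sqrt(0.95 * 0.05 / n)
        assert abs(events / n - 0.95) < 3 * se


class TestMutate:
    def test_rate_zero_is_identity(self, demo_space):
        ind = em.init_generation(demo_space, em.GAConfig(seed=2)).individuals[0]
        out, flipped = em.mutate(
            ind, em.GAConfig(mutation_rate=0.0), np.random.default_rng(0), demo_space
        )
        assert out.key == ind.key and flipped == []

    def test_rate_one_is_complement(self, demo_space):
        ind = em.init_generation(demo_space, em.GAConfig(seed=2)).individuals[0]
        out, flipped = em.mutate(
            ind, em.GAConfig(mutation_rate=1.0), np.random.default_rng(0), demo_space
        )
        assert np.array_equal(out.chromosome, 1 - ind.chromosome)
        assert len(flipped) == ind.chromosome.size

    def test_flip_rate_matches_config(self, aa_space):
        rng = np.random.default_rng(12)
        ind = em.init_generation(aa_space, em.GAConfig(seed=3)).individuals[0]
        total_bits, flips = 0, 0
        while total_bits < 100_000:
            _, flipped = em.mutate(ind, em.GAConfig(), rng, aa_space)
            flips += len(flipped)
            total_bits += ind.chromosome.size
        se = np.sqrt(0.02 * 0.98 / total_bits)
        assert abs(flips / total_bits - 0.02) < 3 * se


class TestNextGeneration:
    def test_breeds_thirty_unique_offspring(self, aa_space):
        rng = np.random.default_rng(0)
        gen = em.init_generation(aa_space, em.GAConfig(seed=4))
        scored(gen.individuals, np.linspace(1.0, 1.5, 30))
        nxt = em.next_generation(gen, em.GAConfig(), aa_space, rng)
        assert nxt.index == 2
        assert len(nxt.individuals) == 30
        assert len({i.key for i in nxt.individuals}) == 30
        assert len(nxt.parent_log) == 30
        assert all(rec["parents"] for rec in nxt.parent_log)

    def test_unscored_population_rejected(self, aa_space):
        gen = em.init_generation(aa_space, em.GAConfig(seed=4))
        with pytest.raises(StateError):
            em.next_generation(gen, em.GAConfig(), aa_space, np.random.default_rng(0))

    def test_no_variation_reproduces_parents(self, demo_space):
        cfg = em.GAConfig(population_size=8, crossover_prob=0.0, mutation_rate=0.0)
        gen = em.init_generation(demo_space, cfg, np.random.default_rng(9))
        scored(gen.individuals, [1.0] * 8)
        nxt = em.next_generation(gen, cfg, demo_space, np.random.default_rng(10))
        assert {i.key for i in nxt.individuals} == {i.key for i in gen.individuals}

    def test_deterministic_under_rng_state(self, aa_space):
        gen = em.init_generation(aa_space, em.GAConfig(seed=6))
        scored(gen.individuals, np.linspace(1.0, 1.6, 30))
        a = em.next_generation(gen, em.GAConfig(), aa_space, np.random.default_rng(77))
        b = em.next_generation(gen, em.GAConfig(), aa_space, np.random.default_rng(77))
        assert [i.key for i in a.individuals] == [i.key for i in b.individuals]

    def test_elitism_carries_best_forward(self, aa_space):
        cfg = em.GAConfig(elitism=1)
        gen = em.init_generation(aa_space, cfg, np.random.default_rng(8))
        scored(gen.individuals, np.linspace(1.0, 1.6, 30))
        best = gen.best()
        nxt = em.next_generation(gen, cfg, aa_space, np.random.default_rng(8))
        assert nxt.individuals[0].key == best.key
        assert nxt.parent_log[0].get("elite") is True

    def test_exhausted_uniqueness_is_degenerate(self):
        space = one_gene_space(3)  # only 4 chromosomes exist
        cfg = em.GAConfig(
            population_size=4, crossover_prob=0.0, mutation_rate=0.0,
            max_redraw_attempts=50,
        )
        gen = em.init_generation(space, cfg, np.random.default_rng(0))
        # selection mass on a single parent: clones can never be unique
        scored(gen.individuals, [1.0, 0.0, 0.0, 0.0])
        cfg_raw = em.GAConfig(**{**cfg.to_dict(), "fitness_scaling": "raw"})
        with pytest.raises(DegeneratePopulationError):
            em.next_generation(gen, cfg_raw, space, np.random.default_rng(1))


class TestCampaign:
    def test_ask_tell_cycle(self, aa_space):
        camp = em.Campaign(aa_space, em.GAConfig(seed=42))
        gen = camp.ask()
        assert gen.index == 1 and len(gen.individuals) == 30
        assert camp.ask() is gen  # idempotent until told
        results = {ind.treatment_id: 1.0 + i / 30 for i, ind in enumerate(gen.individuals)}
        camp.tell(results)
        assert camp.generations[-1].scored
        assert camp.ask().index == 2

    def test_tell_missing_or_extra_ids_rejected(self, aa_space):
        camp = em.Campaign(aa_space, em.GAConfig(seed=1))
        gen = camp.ask()
        results = {ind.treatment_id: 1.0 for ind in gen.individuals[:-1]}
        with pytest.raises(ReconciliationError, match=gen.individuals[-1].treatment_id):
            camp.tell(results)
        results = {ind.treatment_id: 1.0 for ind in gen.individuals}
        results["ghost"] = 2.0
        with pytest.raises(ReconciliationError, match="ghost"):
            camp.tell(results)

    def test_tell_duplicate_id_names_offender(self, aa_space):
        camp = em.Campaign(aa_space, em.GAConfig(seed=1))
        gen = camp.ask()
        df = pd.DataFrame(
            {
                "treatment_id": [i.treatment_id for i in gen.individuals] + ["1-1"],
                "fitness": [1.0] * 31,
            }
        )
        with pytest.raises(ReconciliationError, match="1-1"):
            camp.tell(df)

    def test_tell_floors_negative_fitness(self, aa_space):
        camp = em.Campaign(aa_space, em.GAConfig(seed=1))
        gen = camp.ask()
        results = {ind.treatment_id: -0.5 for ind in gen.individuals}
        results[gen.individuals[0].treatment_id] = 1.0
        camp.tell(results)
        assert camp.generations[-1].individuals[1].fitness == 0.0

    def test_serialization_resume_is_bit_identical(self, aa_space, tmp_path):
        def drive(camp, n):
            out = []
            for g in range(n):
                gen = camp.ask()
                camp.tell({i.treatment_id: 1.0 + (hash(i.key) % 97) / 97 for i in gen.individuals})
                out.append([i.key for i in gen.individuals])
            return out

        ref = em.Campaign(aa_space, em.GAConfig(seed=99))
        ref_gens = drive(ref, 3)

        camp = em.Campaign(aa_space, em.GAConfig(seed=99))
        gens = drive(camp, 2)
        path = tmp_path / "campaign.json"
        camp.save(path)
        resumed = em.Campaign.load(path)
        gens += drive(resumed, 1)
        assert gens == ref_gens

    def test_stagnation_metric(self, aa_space):
        camp = em.Campaign(aa_space, em.GAConfig(seed=3))
        gen = camp.ask()
        camp.tell({i.treatment_id: 1.0 for i in gen.individuals})
        assert camp.stagnation() is None
        gen = camp.ask()
        camp.tell(
            {i.treatment_id: (1.1 if k == 0 else 0.9) for k, i in enumerate(gen.individuals)}
        )
        assert camp.stagnation() == pytest.approx(0.1)
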