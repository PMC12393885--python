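"""Genetic-algorithm operators and full-run invariants."""

import numpy as np
import pytest

from klinosim.circuit import GENOME_LENGTH, Genome
from klinosim.evolution import (
    GAConfig,
    evaluate_fitness,
    mutate,
    run_evolution,
    run_generation,
    select_elite,
    two_point_crossover,
)


def _genomes(n, rng):
    return [Genome.random(rng) for _ in range(n)]


class TestSelectElite:
    def test_selects_largest_fitness(self, rng):
        pop = _genomes(6, rng)
        fit = [0.1, 0.9, 0.3, 0.7, 0.2, 0.8]
        elite = select_elite(pop, fit, 3)
        assert [f for _, f in elite] == [0.9, 0.8, 0.7]

    def test_ties_break_by_original_order(self, rng):
        pop = _genomes(4, rng)
        elite = select_elite(pop, [0.5, 0.5, 0.5, 0.5], 2)
        assert elite[0][0] is pop[0] and elite[1][0] is pop[1]

    def test_full_population_selection_is_fitness_sort(self, rng):
        pop = _genomes(5, rng)
        fit = [0.3, 0.1, 0.5, 0.2, 0.4]
        elite = select_elite(pop, fit, 5)
        assert [f for _, f in elite] == sorted(fit, reverse=True)


class _CutRng:
    """Stub generator forcing the two crossover cut points."""

    def __init__(self, lo, hi):
        self._cuts = np.array([lo, hi])

    def integers(self, *a, **k):
        return self._cuts


class TestCrossover:
    def test_identical_parents_give_identical_children(self, rng):
        g = Genome.random(rng)
        c1, c2 = two_point_crossover(g, g, rng)
        assert c1.values == g.values and c2.values == g.values

    def test_full_segment_swap_exchanges_parents(self, rng):
        a, b = _genomes(2, rng)
        c1, c2 = two_point_crossover(a, b, _CutRng(0, GENOME_LENGTH))
        assert c1.values == b.values and c2.values == a.values

    def test_gene_multiset_is_conserved(self, rng):
        a, b = _genomes(2, rng)
        c1, c2 = two_point_crossover(a, b, rng)
        parents = sorted(a.values + b.values)
        children = sorted(c1.values + c2.values)
        assert parents == pytest.approx(children)


class TestMutate:
    def test_zero_sd_leaves_genome_unchanged(self, rng):
        g = Genome.random(rng)
        assert mutate(g, rng, per_element_p=0.4, sd=0.0).values == g.values

    def test_zero_probability_leaves_genome_unchanged(self, rng):
        g = Genome.random(rng)
        assert mutate(g, rng, per_element_p=0.0, sd=0.05).values == g.values

    def test_monte_carlo_rates_match_settings(self, rng):
        zero = Genome.from_array([0.0] * GENOME_LENGTH)
        n = 100_000
        changed = 0
        perturbations = []
        for _ in range(n // 100):
            for _ in range(100):
                m = np.asarray(mutate(zero, rng).values)
                nz = m != 0.0
                changed += int(nz.sum())
                perturbations.extend(m[nz])
        frac = changed / (n * GENOME_LENGTH)
        assert frac == pytest.approx(0.4, abs=0.01)
        assert np.std(perturbations) == pytest.approx(0.05, abs=0.002)

    def test_mutants_stay_in_genome_box(self, rng):
        edge = Genome.from_array([1.0] * GENOME_LENGTH)
        for _ in range(50):
            m = mutate(edge, rng, per_element_p=1.0, sd=0.5)
            assert all(-1.0 <= v <= 1.0 for v in m.values)


class TestRunGeneration:
    def _elite(self, rng, k=20):
        return [(g, 1.0 - i * 0.01) for i, g in enumerate(_genomes(k, rng))]

    def test_degenerate_probabilities_give_elites_plus_randoms(self, rng):
        cfg = GAConfig(crossover_p=0.0, mutation_p=0.0)
        elite = self._elite(rng)
        pop, fit, needs = run_generation(elite, cfg, rng)
        assert len(pop) == 60
        assert needs[:20] == [False] * 20 and all(needs[20:])
        assert [g.values for g in pop[:20]] == [g.values for g, _ in elite]

    def test_population_size_is_always_exact(self, rng):
        cfg = GAConfig(crossover_p=1.0, mutation_p=1.0)
        pop, fit, needs = run_generation(self._elite(rng), cfg, rng)
        assert len(pop) == len(fit) == len(needs) == 60

    def test_elite_fitness_is_carried_not_reevaluated(self, rng):
        cfg = GAConfig()
        elite = self._elite(rng)
        pop, fit, needs = run_generation(elite, cfg, rng)
        assert fit[:20] == [f for _, f in elite]


class TestRunEvolution:
    @staticmethod
    def _surrogate(genome, cfg, rng):
        # cheap deterministic stand-in: reward genomes near +1 everywhere
        return float(np.mean(genome.as_array()))

    def test_best_fitness_is_non_decreasing(self, rng):
        cfg = GAConfig(population=20, elite=6, generations=15, seed=5)
        res = run_evolution(cfg, evaluate=self._surrogate)
        best = [h["best"] for h in res.history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
        assert res.best_fitness == best[-1]

    def test_same_seed_reproduces_the_run(self):
        cfg = GAConfig(population=16, elite=4, generations=8, seed=11)
        r1 = run_evolution(cfg, evaluate=self._surrogate)
        r2 = run_evolution(cfg, evaluate=self._surrogate)
        assert r1.best_genome.values == r2.best_genome.values
        assert r1.history == r2.history

    def test_all_genomes_stay_valid(self):
        seen = []

        def spy(genome, cfg, rng):
            seen.append(genome)
            return self._surrogate(genome, cfg, rng)

        cfg = GAConfig(population=12, elite=4, generations=10, seed=2)
        run_evolution(cfg, evaluate=spy)
        for g in seen:
            assert len(g.values) == GENOME_LENGTH
            assert all(-1.0 <= v <= 1.0 for v in g.values)


class TestEnsemble:
    @staticmethod
    def _surrogate(genome, cfg, rng):
        return float(np.mean(genome.as_array()))

    def test_results_sorted_by_fitness_and_gaussian_rankable(self):
        import klinosim.evolution as evo

        cfg = GAConfig(population=10, elite=3, generations=3, seed=9)
        results = evo.run_evolution_ensemble(
            cfg, n_runs=3, evaluate_gaussian=True,
            evaluate=self._surrogate,
            gaussian_evaluate=lambda g, cfg, rng, trials=1: -float(
                np.mean(g.as_array())))
        fits = [r.best_fitness for r in results]
        assert fits == sorted(fits, reverse=True)
        by_ci = evo.rank_by_gaussian_ci(results)
        cis = [r.gaussian_ci for r in by_ci]
        assert cis == sorted(cis, reverse=True)


class TestEvaluateFitness:
    def test_straight_mover_without_undulation_scores_zero(self):
        # all weights zero and no oscillation: the undulation penalty
        # outweighs any incidental approach to the peak
        vals = [0.0] * GENOME_LENGTH
        vals[-2] = -1.0  # oscillator strength -> 0
        genome = Genome.from_array(vals)
        cfg = GAConfig(fitness_trials=5, t_sim_evolution=500.0, seed=0)
        fitness = evaluate_fitness(genome, cfg, np.random.default_rng(0))
        assert fitness == 0.0

    def test_deterministic_given_generator_state(self):
        genome = Genome.from_array(np.linspace(-0.5, 0.5, GENOME_LENGTH))
        cfg = GAConfig(fitness_trials=1, t_sim_evolution=100.0)
        f1 = evaluate_fitness(genome, cfg, np.random.default_rng(42))
        f2 = evaluate_fitness(genome, cfg, np.random.default_rng(42))
        assert f1 == f2

    def test_fitness_estimate_is_stable_across_trial_counts(self):
        # the trial average estimates the same quantity at any trial count
        genome = Genome.from_array(np.linspace(-0.6, 0.6, GENOME_LENGTH))
        few = GAConfig(fitness_trials=15, t_sim_evolution=100.0)
        many = GAConfig(fitness_trials=60, t_sim_evolution=100.0)
        f_few = evaluate_fitness(genome, few, np.random.default_rng(1))
        f_many = evaluate_fitness(genome, many, np.random.default_rng(2))
        assert f_few == pytest.approx(f_many, abs=0.15)

    def test_fitness_is_clamped_to_unit_interval(self, rng):
        cfg = GAConfig(fitness_trials=2, t_sim_evolution=100.0)
        for _ in range(5):
            f = evaluate_fitness(Genome.random(rng), cfg, rng)
            assert 0.0 <= f <= 1.0
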