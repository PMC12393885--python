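"""Genetic-algorithm search over the 22 circuit parameters.

A population of 60 genomes evolves for 300 generations.  Fitness is the
chemotaxis index (penalty enabled) averaged over 50 conical assays whose
gradient steepness, initial orientation and initial motor activations are
randomized per trial.  Each generation copies the 20 fittest genomes
verbatim, adds two-point-crossover children of consecutive elite pairs
(each pair crossing with probability 0.6), adds Gaussian mutants of elite
members (each elite selected with probability 0.5; selected genes perturbed
with probability 0.4 by noise of SD 0.05, clipped to [-1, 1]) and refills
to 60 with fresh random genomes.

Each genome is evaluated once, when it is created; elite copies carry their
fitness forward, which makes the recorded best fitness non-decreasing and
avoids re-spending trials on unchanged individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .circuit import (
    CircuitParameters,
    GENOME_LENGTH,
    Genome,
    ParameterRanges,
    decode_genome,
)
from .environment import Environment
from .errors import InvalidParameterError
from .simulator import AssayConfig, chemotaxis_index, run_assay


@dataclass
class GAConfig:
    """Settings of the evolutionary search.

    Defaults are the full-fidelity study conditions; scaled-down settings
    (smaller population, fewer generations/trials, shorter assays) are for
    desk-scale experiments and tests.
    """

    population: int = 60
    elite: int = 20
    generations: int = 300
    crossover_p: float = 0.6
    mutation_p: float = 0.5
    per_element_p: float = 0.4
    mutation_sd: float = 0.05
    fitness_trials: int = 50
    alpha_range: tuple[float, float] = (-0.38, -0.01)
    peak: tuple[float, float] = (4.5, 0.0)
    t_sim_evolution: float = 500.0
    t_sim_evaluation: float = 1000.0
    dt: float = 0.01
    runs: int = 100
    constrain_aiy_aiz: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.crossover_p, self.mutation_p, self.per_element_p):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError("probabilities must lie in [0, 1]")
        if self.elite > self.population:
            raise InvalidParameterError("elite count cannot exceed population")


@dataclass
class EvolutionResult:
    """Outcome of one GA run: history, final elite and the best genome."""

    best_genome: Genome
    best_fitness: float
    elite: list[tuple[Genome, float]]
    history: list[dict] = field(default_factory=list)
    config: GAConfig | None = None
    gaussian_ci: float | None = None


def _decode(genome: Genome, cfg: GAConfig) -> CircuitParameters:
    return decode_genome(genome, ParameterRanges.default(),
                         constrain_aiy_aiz=cfg.constrain_aiy_aiz)


def evaluate_fitness(genome: Genome, cfg: GAConfig,
                     rng: np.random.Generator) -> float:
    """Mean penalized CI over randomized conical assays.

    Each trial draws the conical slope uniformly from ``alpha_range``, the
    initial orientation from [0, 2*pi) and the four motor activations from
    [0, 1]; the worm starts at the origin with the peak at ``cfg.peak``.
    """
    params = _decode(genome, cfg)
    total = 0.0
    for _ in range(cfg.fitness_trials):
        alpha = float(rng.uniform(*cfg.alpha_range))
        env = Environment.conical(alpha=alpha, peak=cfg.peak)
        config = AssayConfig(
            environment=env, duration=cfg.t_sim_evolution, dt=cfg.dt,
            start=(0.0, 0.0),
            initial_heading=float(rng.uniform(0.0, 2.0 * math.pi)),
            initial_motor_z={
                n: float(rng.uniform(0.0, 1.0))
                for n in ("SMBDL", "SMBVL", "SMBDR", "SMBVR")
            },
        )
        traj = run_assay(params, config)
        total += chemotaxis_index(traj, env, penalty_enabled=True,
                                  params=params)
    return total / cfg.fitness_trials


def evaluate_gaussian_ci(genome: Genome, cfg: GAConfig,
                         rng: np.random.Generator,
                         trials: int | None = None,
                         penalty_enabled: bool = False) -> float:
    """Mean CI on the Gaussian plate (evaluation mode, T_sim_evaluation)."""
    params = _decode(genome, cfg)
    env = Environment.gaussian(peak=cfg.peak)
    trials = trials if trials is not None else cfg.fitness_trials
    total = 0.0
    for _ in range(trials):
        config = AssayConfig(
            environment=env, duration=cfg.t_sim_evaluation, dt=cfg.dt,
            start=(0.0, 0.0),
            initial_heading=float(rng.uniform(0.0, 2.0 * math.pi)),
            initial_motor_z={
                n: float(rng.uniform(0.0, 1.0))
                for n in ("SMBDL", "SMBVL", "SMBDR", "SMBVR")
            },
        )
        traj = run_assay(params, config)
        total += chemotaxis_index(traj, env, penalty_enabled=penalty_enabled,
                                  params=params)
    return total / trials


def select_elite(population: list[Genome], fitness: list[float],
                 k: int) -> list[tuple[Genome, float]]:
    """Top-k genomes by fitness; ties broken by original (stable) index."""
    if len(population) < k:
        raise InvalidParameterError("population smaller than elite count")
    order = sorted(range(len(population)), key=lambda i: (-fitness[i], i))
    return [(population[i], fitness[i]) for i in order[:k]]


def two_point_crossover(parent_a: Genome, parent_b: Genome,
                        rng: np.random.Generator) -> tuple[Genome, Genome]:
    """Swap the segment between two uniform cut points of the two parents."""
    a = parent_a.as_array().copy()
    b = parent_b.as_array().copy()
    cuts = sorted(rng.integers(0, GENOME_LENGTH + 1, size=2))
    lo, hi = int(cuts[0]), int(cuts[1])
    a[lo:hi], b[lo:hi] = b[lo:hi].copy(), a[lo:hi].copy()
    return Genome.from_array(a), Genome.from_array(b)


def mutate(genome: Genome, rng: np.random.Generator,
           per_element_p: float = 0.4, sd: float = 0.05) -> Genome:
    """Perturb each gene with probability ``per_element_p`` by N(0, sd^2),
    clipping the result to [-1, 1]."""
    x = genome.as_array().copy()
    mask = rng.uniform(size=GENOME_LENGTH) < per_element_p
    noise = rng.normal(0.0, sd, size=GENOME_LENGTH) if sd > 0 else 0.0
    x = np.where(mask, np.clip(x + noise, -1.0, 1.0), x)
    return Genome.from_array(x)


def run_generation(
    elite: list[tuple[Genome, float]],
    cfg: GAConfig,
    rng: np.random.Generator,
    evaluate=evaluate_fitness,
) -> tuple[list[Genome], list[float], list[bool]]:
    """Compose the next population from a ranked elite.

    Returns the new population, a fitness list with cached values for the
    carried-over elite (others NaN), and a mask of which members still need
    evaluation.  Elite copies come first, then crossover children of
    consecutive elite pairs, then mutants, then random refill; extras beyond
    the population size are truncated from the end.
    """
    population: list[Genome] = [g for g, _ in elite]
    fitness: list[float] = [f for _, f in elite]
    needs_eval: list[bool] = [False] * len(elite)

    def add(genome: Genome) -> None:
        population.append(genome)
        fitness.append(float("nan"))
        needs_eval.append(True)

    for i in range(0, len(elite) - 1, 2):
        if rng.uniform() < cfg.crossover_p:
            c1, c2 = two_point_crossover(elite[i][0], elite[i + 1][0], rng)
            add(c1)
            add(c2)
    for genome, _ in elite:
        if rng.uniform() < cfg.mutation_p:
            add(mutate(genome, rng, cfg.per_element_p, cfg.mutation_sd))
    while len(population) < cfg.population:
        add(Genome.random(rng))
    population = population[: cfg.population]
    fitness = fitness[: cfg.population]
    needs_eval = needs_eval[: cfg.population]
    return population, fitness, needs_eval


def run_evolution(cfg: GAConfig, rng: np.random.Generator | None = None,
                  evaluate=evaluate_fitness,
                  progress: bool = False) -> EvolutionResult:
    """Run one full GA and return the ranked outcome.

    ``evaluate`` may be swapped for a surrogate in tests.  Reproducible
    given ``cfg.seed`` (or an explicitly passed generator).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    population = [Genome.random(rng) for _ in range(cfg.population)]
    fitness = [evaluate(g, cfg, rng) for g in population]
    history: list[dict] = []
    elite = select_elite(population, fitness, cfg.elite)
    for gen in range(cfg.generations):
        population, fitness, needs_eval = run_generation(elite, cfg, rng,
                                                         evaluate)
        for i, todo in enumerate(needs_eval):
            if todo:
                fitness[i] = evaluate(population[i], cfg, rng)
        elite = select_elite(population, fitness, cfg.elite)
        stats = {
            "generation": gen + 1,
            "best": elite[0][1],
            "mean": float(np.mean(fitness)),
            "elite_mean": float(np.mean([f for _, f in elite])),
        }
        history.append(stats)
        if progress:
            print(f"gen {gen + 1:4d}  best {stats['best']:.4f}  "
                  f"mean {stats['mean']:.4f}")
    best_genome, best_fitness = elite[0]
    return EvolutionResult(best_genome=best_genome, best_fitness=best_fitness,
                           elite=elite, history=history, config=cfg)


def run_evolution_ensemble(cfg: GAConfig, n_runs: int | None = None,
                           evaluate_gaussian: bool = False,
                           gaussian_trials: int = 20,
                           evaluate=evaluate_fitness,
                           gaussian_evaluate=evaluate_gaussian_ci,
                           progress: bool = False) -> list[EvolutionResult]:
    """Repeat the GA ``n_runs`` times with independent sub-seeded streams and
    return the results sorted by best fitness (descending).

    With ``evaluate_gaussian`` each run's best genome is additionally scored
    on the Gaussian plate (``gaussian_ci`` attribute on the results), the
    alternative ranking criterion for the run ensemble; use
    :func:`rank_by_gaussian_ci` to re-order by it.
    """
    n_runs = n_runs if n_runs is not None else cfg.runs
    seeds = np.random.SeedSequence(cfg.seed).spawn(2 * n_runs)
    results = []
    for k in range(n_runs):
        run_cfg = replace(cfg, seed=None)
        res = run_evolution(run_cfg, rng=np.random.default_rng(seeds[k]),
                            evaluate=evaluate, progress=progress)
        res.gaussian_ci = (
            gaussian_evaluate(res.best_genome, cfg,
                              np.random.default_rng(seeds[n_runs + k]),
                              trials=gaussian_trials)
            if evaluate_gaussian else None)
        results.append(res)
        if progress:
            print(f"run {k + 1}/{n_runs}: best fitness {res.best_fitness:.4f}")
    results.sort(key=lambda r: -r.best_fitness)
    return results


def rank_by_gaussian_ci(results: list[EvolutionResult]) -> list[EvolutionResult]:
    """Order ensemble results by their Gaussian-plate CI (descending)."""
    if any(r.gaussian_ci is None for r in results):
        raise InvalidParameterError(
            "results lack gaussian_ci; rerun the ensemble with "
            "evaluate_gaussian=True")
    return sorted(results, key=lambda r: -r.gaussian_ci)
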