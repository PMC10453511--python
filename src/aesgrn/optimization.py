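"""Genetic algorithm assigning one architecture to each agent.

A solution is a length-n vector over {FCNN, CNN, RNN}.  Fitness is the
negative environment-level MSE of the assembled simulator against the
evaluation target, so higher is better.  Trained agents are cached per
(gene, architecture): an assignment differing in one gene from an already
evaluated one costs one extra training run.

The GA is generational with tournament selection (size 3), uniform
crossover, per-gene uniform-reassignment mutation, and elitism of one;
every fitness call counts against the evaluation budget, cache hits
included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .agents import ARCHITECTURES, Agent, make_agent
from .datasets import SupervisedSet
from .environment import AES, StateMatrix, seed_initial_state
from .errors import AesgrnError, SpecError
from .evaluation import evaluate_aes

__all__ = ["GAConfig", "ArchitectureAssignment", "FitnessEvaluator", "run_ga"]

logger = logging.getLogger(__name__)


@dataclass
class GAConfig:
    population_size: int = 10
    mutation_prob: float = 0.2
    crossover_prob: float = 0.8
    tournament_size: int = 3
    max_evaluations: int = 100
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.mutation_prob, self.crossover_prob):
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"probability {p} outside [0, 1]")
        if min(self.population_size, self.tournament_size, self.max_evaluations) < 1:
            raise SpecError("population, tournament and budget must be >= 1")
        if self.max_evaluations < self.population_size:
            raise SpecError("evaluation budget must cover the initial population")


@dataclass
class ArchitectureAssignment:
    assignment: tuple[str, ...]
    fitness: float


class FitnessEvaluator:
    """Builds the simulator for an assignment and scores it.

    ``supervised`` maps gene index -> that gene's training set;
    ``eval_target`` is the (n, b) experiment-averaged target whose first m
    columns seed the simulation.  Returns -Err_MSE; a failed training run
    scores -inf.
    """

    def __init__(
        self,
        supervised: Sequence[SupervisedSet],
        eval_target: np.ndarray,
        m: int,
        tuning_budget: int = 0,
        seed: int = 0,
        clip: tuple[float, float] | None = (0.0, 1.5),
    ):
        self.supervised = list(supervised)
        self.eval_target = np.asarray(eval_target, float)
        self.m = m
        self.tuning_budget = tuning_budget
        self.seed = seed
        self.clip = clip
        self.cache: dict[tuple[int, str], Agent] = {}
        ss = np.random.SeedSequence(seed)
        n = len(self.supervised)
        self._agent_seeds = {
            (i, arch): int(s.generate_state(1)[0] % (2**31))
            for (i, arch), s in zip(
                [(i, a) for i in range(n) for a in ARCHITECTURES],
                ss.spawn(n * len(ARCHITECTURES)),
            )
        }

    def agent_for(self, gene_index: int, architecture: str) -> Agent:
        key = (gene_index, architecture)
        if key not in self.cache:
            self.cache[key] = make_agent(
                architecture,
                self.supervised[gene_index],
                tuning_budget=self.tuning_budget,
                seed=self._agent_seeds[key],
            )
        return self.cache[key]

    def __call__(self, assignment: Sequence[str]) -> float:
        try:
            agents = [self.agent_for(i, a) for i, a in enumerate(assignment)]
            aes = AES(agents, clip=self.clip)
            initial = seed_initial_state(self.eval_target.T, self.m)
            trace = aes.simulate(initial, self.eval_target.shape[1])
            report = evaluate_aes(trace, self.eval_target, self.m)
            return -report.err_mse
        except AesgrnError as exc:
            logger.warning("fitness evaluation failed for %s: %s", assignment, exc)
            return -np.inf


def run_ga(
    config: GAConfig,
    fitness_fn: Callable[[tuple[str, ...]], float],
    n: int,
    architectures: Sequence[str] = ARCHITECTURES,
    initial: Sequence[Sequence[str]] | None = None,
) -> tuple[ArchitectureAssignment, list[dict]]:
    """Maximize fitness over assignments; returns best-ever plus the full log.

    ``initial`` optionally seeds the first population (e.g. with the three
    uniform single-architecture assignments); the remainder is random.
    The log records every evaluation in order: repeated genotypes are
    re-logged (their fitness comes from the caller's cache) and still
    consume budget.
    """
    if n < 1:
        raise SpecError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    archs = tuple(architectures)
    history: list[dict] = []
    best: ArchitectureAssignment | None = None

    def evaluate(ind: tuple[str, ...]) -> float:
        nonlocal best
        fit = fitness_fn(ind)
        history.append({"evaluation": len(history), "solution": ind, "fitness": fit})
        if best is None or fit > best.fitness:
            best = ArchitectureAssignment(ind, fit)
        return fit

    def random_individual() -> tuple[str, ...]:
        return tuple(archs[i] for i in rng.integers(len(archs), size=n))

    population = [tuple(ind) for ind in (initial or [])][: config.population_size]
    for ind in population:
        if any(a not in archs for a in ind) or len(ind) != n:
            raise SpecError(f"seeded individual {ind} outside the search domain")
    while len(population) < config.population_size:
        population.append(random_individual())
    fitnesses = [evaluate(ind) for ind in population]

    def tournament() -> tuple[str, ...]:
        idx = rng.integers(len(population), size=config.tournament_size)
        return population[max(idx, key=lambda i: fitnesses[i])]

    while len(history) < config.max_evaluations:
        order = np.argsort(fitnesses)[::-1]
        elite = [population[i] for i in order[: config.elitism]]
        elite_fits = [fitnesses[i] for i in order[: config.elitism]]
        offspring: list[tuple[str, ...]] = []
        while len(offspring) < config.population_size - config.elitism:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_prob:
                child = tuple(
                    p1[i] if rng.random() < 0.5 else p2[i] for i in range(n)
                )
            else:
                child = p1
            child = tuple(
                archs[rng.integers(len(archs))] if rng.random() < config.mutation_prob else g
                for g in child
            )
            offspring.append(child)
        room = config.max_evaluations - len(history)
        offspring = offspring[:room]
        off_fits = [evaluate(ind) for ind in offspring]
        population = elite + offspring
        fitnesses = elite_fits + off_fits
    assert best is not None
    return best, history
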