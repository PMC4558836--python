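"""Genetic algorithm over mixed continuous/integer/boolean/categorical genes.

Each workflow parameter is encoded as one gene on a chromosome; a chromosome
is one candidate parameter combination.  Genes may be linked (equality to
another gene) or constrained (this gene <= another), with violations
repaired by copying/clipping the dependent gene.  Selection is by
tournament, variation by single-point crossover (with blending of
continuous genes) and per-gene mutation, and elitism guarantees that the
best fitness never decreases across generations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


class GeneKind(str, Enum):
    CONTINUOUS = "continuous"
    INTEGER = "integer"
    BOOLEAN = "boolean"
    CATEGORICAL = "categorical"


@dataclass(frozen=True)
class ParamSpec:
    """One optimizable parameter: kind, range/categories, dependency.

    ``equal_to`` links this gene to another (its value is always copied
    from the source); ``at_most`` constrains this gene to be <= another,
    repaired by clipping this (the dependent) gene.
    """

    name: str
    kind: GeneKind
    low: float | None = None
    high: float | None = None
    categories: tuple | None = None
    equal_to: str | None = None
    at_most: str | None = None

    def __post_init__(self):
        kind = GeneKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind in (GeneKind.CONTINUOUS, GeneKind.INTEGER):
            if self.low is None or self.high is None or not self.low < self.high:
                raise ValueError(f"{self.name}: need low < high")
        if kind is GeneKind.CATEGORICAL and not self.categories:
            raise ValueError(f"{self.name}: need categories")


@dataclass
class Chromosome:
    """One candidate parameter combination with (optional) fitness."""

    values: tuple
    fitness: float | None = None

    def as_dict(self, spec: Sequence) -> dict:
        return {s.name: v for s, v in zip(spec, self.values)}


@dataclass
class GAConfig:
    population: int = 20
    max_generations: int = 30
    crossover_prob: float = 0.7
    mutation_prob_per_gene: float = 0.1
    tournament_size: int = 2
    elitism: int = 1
    stagnation_limit: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.elitism < self.population:
            raise ValueError("elitism must be in [0, population)")


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_values: tuple
    evaluations: int


def _check_spec(spec: Sequence) -> dict:
    names = {s.name: i for i, s in enumerate(spec)}
    if len(names) != len(spec):
        raise ValueError("duplicate parameter names")
    # dependency graph must be acyclic
    for s in spec:
        for dep in (s.equal_to, s.at_most):
            if dep is not None and dep not in names:
                raise ValueError(f"{s.name}: unknown dependency {dep!r}")
    seen: dict = {}

    def visit(name, stack):
        if name in stack:
            raise ValueError("dependency cycle involving " + name)
        if seen.get(name):
            return
        s = spec[names[name]]
        for dep in (s.equal_to, s.at_most):
            if dep is not None:
                visit(dep, stack | {name})
        seen[name] = True

    for s in spec:
        visit(s.name, set())
    return names


def validate(spec: Sequence, values: Sequence) -> Chromosome:
    """Range-check values and repair dependency violations.

    Equality-linked genes are copied from their source; ``at_most``
    violations are repaired by clipping the dependent gene down.  A value
    outside its range (and not repairable by a dependency) is rejected.
    """
    names = _check_spec(spec)
    if len(values) != len(spec):
        raise ValueError("one value per parameter required")
    vals = list(values)
    for i, s in enumerate(spec):
        v = vals[i]
        if s.kind is GeneKind.CONTINUOUS:
            v = float(v)
        elif s.kind is GeneKind.INTEGER:
            if float(v) != int(v):
                raise ValueError(f"{s.name}: non-integer value {v!r}")
            v = int(v)
        elif s.kind is GeneKind.BOOLEAN:
            if v not in (0, 1, True, False):
                raise ValueError(f"{s.name}: non-boolean value {v!r}")
            v = bool(v)
        else:
            if v not in s.categories:
                raise ValueError(f"{s.name}: {v!r} not in categories")
        if s.kind in (GeneKind.CONTINUOUS, GeneKind.INTEGER):
            if not s.low <= v <= s.high:
                raise ValueError(f"{s.name}: {v!r} outside [{s.low}, {s.high}]")
        vals[i] = v
    # resolve dependencies in topological passes (graph is acyclic and
    # shallow; iterate until fixed point)
    for _ in range(len(spec)):
        changed = False
        for i, s in enumerate(spec):
            if s.equal_to is not None:
                src = vals[names[s.equal_to]]
                if vals[i] != src:
                    vals[i] = src
                    changed = True
            if s.at_most is not None:
                bound = vals[names[s.at_most]]
                if vals[i] > bound:
                    vals[i] = int(bound) if s.kind is GeneKind.INTEGER else bound
                    changed = True
        if not changed:
            break
    return Chromosome(values=tuple(vals))


def _random_gene(s: ParamSpec, rng: np.random.Generator):
    if s.kind is GeneKind.CONTINUOUS:
        return float(rng.uniform(s.low, s.high))
    if s.kind is GeneKind.INTEGER:
        return int(rng.integers(int(s.low), int(s.high) + 1))
    if s.kind is GeneKind.BOOLEAN:
        return bool(rng.integers(0, 2))
    return s.categories[int(rng.integers(0, len(s.categories)))]


def init_population(spec: Sequence, cfg: GAConfig, rng: np.random.Generator) -> list:
    """Uniform random population, validated; deterministic given the rng."""
    return [
        validate(spec, [_random_gene(s, rng) for s in spec])
        for _ in range(cfg.population)
    ]


def evaluate_generation(population: list, objective: Callable) -> list:
    """Evaluate each chromosome; a failing objective scores 0.

    Evaluations share no mutable state, so results are independent of
    evaluation order.
    """
    fitnesses = []
    for chrom in population:
        try:
            f = float(objective(chrom))
        except Exception:
            logger.warning("objective failed for %s; fitness set to 0",
                           chrom.values, exc_info=True)
            f = 0.0
        chrom.fitness = f
        fitnesses.append(f)
    return fitnesses


def _tournament(fitnesses, cfg, rng) -> int:
    picks = rng.integers(0, len(fitnesses), size=cfg.tournament_size)
    return int(max(picks, key=lambda i: fitnesses[i]))


def _mutate_gene(v, s: ParamSpec, rng):
    if s.kind is GeneKind.CONTINUOUS:
        sigma = 0.1 * (s.high - s.low)
        return float(np.clip(v + rng.normal(0.0, sigma), s.low, s.high))
    if s.kind is GeneKind.INTEGER:
        step = 1 if rng.random() < 0.5 else -1
        return int(np.clip(v + step, int(s.low), int(s.high)))
    if s.kind is GeneKind.BOOLEAN:
        return not v
    return s.categories[int(rng.integers(0, len(s.categories)))]


def next_generation(
    population: list,
    fitnesses: Sequence,
    spec: Sequence,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> list:
    """Elitism + tournament selection + crossover + mutation, validated."""
    if len(population) != len(fitnesses):
        raise ValueError("population/fitness size mismatch")
    order = sorted(range(len(population)), key=lambda i: -fitnesses[i])
    new = [Chromosome(values=population[i].values, fitness=fitnesses[i])
           for i in order[: cfg.elitism]]
    n_genes = len(spec)
    while len(new) < cfg.population:
        a = list(population[_tournament(fitnesses, cfg, rng)].values)
        b = list(population[_tournament(fitnesses, cfg, rng)].values)
        if rng.random() < cfg.crossover_prob and n_genes > 1:
            cut = int(rng.integers(1, n_genes))
            a, b = a[:cut] + b[cut:], b[:cut] + a[cut:]
            for i, s in enumerate(spec):
                if s.kind is GeneKind.CONTINUOUS:
                    alpha = rng.random()
                    ai, bi = a[i], b[i]
                    a[i] = alpha * ai + (1 - alpha) * bi
                    b[i] = alpha * bi + (1 - alpha) * ai
        for child in (a, b):
            for i, s in enumerate(spec):
                if rng.random() < cfg.mutation_prob_per_gene:
                    child[i] = _mutate_gene(child[i], s, rng)
            if len(new) < cfg.population:
                new.append(validate(spec, child))
    return new


def run_ga(
    spec: Sequence,
    objective: Callable,
    cfg: GAConfig,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Run the genetic algorithm; returns (best chromosome, generation log).

    Stops after ``max_generations`` or once the best fitness has not
    improved for ``stagnation_limit`` consecutive generations.  Fully
    deterministic for a fixed (spec, objective, cfg, seed).
    """
    _check_spec(spec)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    population = init_population(spec, cfg, rng)
    log: list = []
    best: Chromosome | None = None
    stagnation = 0
    evaluations = 0
    for gen in range(cfg.max_generations):
        fitnesses = evaluate_generation(population, objective)
        evaluations += len(population)
        gen_best = max(range(len(population)), key=lambda i: fitnesses[i])
        improved = best is None or fitnesses[gen_best] > best.fitness
        if improved:
            best = Chromosome(values=population[gen_best].values,
                              fitness=fitnesses[gen_best])
            stagnation = 0
        else:
            stagnation += 1
        log.append(
            GenerationRecord(
                generation=gen,
                best_fitness=best.fitness,
                mean_fitness=float(np.mean(fitnesses)),
                best_values=best.values,
                evaluations=evaluations,
            )
        )
        if stagnation >= cfg.stagnation_limit:
            break
        if gen < cfg.max_generations - 1:
            population = next_generation(population, fitnesses, spec, cfg, rng)
    return best, log
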