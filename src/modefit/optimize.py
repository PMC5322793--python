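"""Random-search and genetic-algorithm drivers for the conditional objective.

Both optimizers minimize the precondition-gated objective over a box
parameter space, drawing candidates uniformly on the linear scale of the
bounds.  Rejected candidates (failed precondition) cost only a
deterministic steady-state analysis; the stochastic ensemble runs only for
accepted ones.  All randomness — candidate draws, crossover, mutation and
the per-evaluation ensemble seeds — derives from one base seed, so a fit
is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from typing import Sequence

import numpy as np

from .distributions import (
    EventTable,
    FcondConfig,
    ModeSet,
    distributions_from_events,
    find_modes,
    objective_Fcond,
)
from .models import ParameterSet, ParameterSpace, ReactionNetwork


class OptimizerConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    The population is adaptive: a large uniformly sampled generation 0
    (sized to survive the heavy precondition rejection) followed by small
    subsequent generations.  ``elitism`` is the fraction of the next
    generation's size kept as ranked parents; ``mutation`` is the per-gene
    probability of uniform resampling within bounds.
    """

    initial_population: int = 3000
    population: int = 20
    generations: int = 5
    elitism: float = 0.4
    mutation: float = 0.2

    def __post_init__(self) -> None:
        if not (0 < self.elitism <= 1):
            raise OptimizerConfigError("elitism must be in (0, 1]")
        if not (0 <= self.mutation <= 1):
            raise OptimizerConfigError("mutation must be in [0, 1]")
        if self.initial_population < 2 or self.population < 2:
            raise OptimizerConfigError("population sizes must be >= 2")
        if self.generations < 1:
            raise OptimizerConfigError("generations must be >= 1")
        if ceil(self.elitism * self.population) < 2:
            raise OptimizerConfigError("fewer than 2 parents after elitism")


@dataclass
class EvalRecord:
    params: dict
    value: float
    passed: bool
    n_ssa_runs: int
    index: int
    generation: int | None = None


@dataclass
class FitResult:
    """Outcome of one optimization run."""

    best_params: ParameterSet
    best_value: float
    trace: list[EvalRecord]
    base_seed: int
    config: dict
    #: best objective in the population after each generation (GA only);
    #: non-increasing by the elitist carry-over
    generation_best: list[float] = field(default_factory=list)

    @property
    def n_evaluations(self) -> int:
        return len(self.trace)

    @property
    def pass_rate(self) -> float:
        """Fraction of evaluated parameter sets that passed the precondition."""
        return sum(r.passed for r in self.trace) / max(1, len(self.trace))

    def pass_rate_by_generation(self) -> dict[int, float]:
        gens: dict[int, list[bool]] = {}
        for r in self.trace:
            gens.setdefault(r.generation or 0, []).append(r.passed)
        return {g: sum(v) / len(v) for g, v in sorted(gens.items())}

    def best_by_generation(self) -> dict[int, float]:
        gens: dict[int, float] = {}
        for r in self.trace:
            g = r.generation or 0
            gens[g] = min(gens.get(g, np.inf), r.value)
        # running minimum: the elitist carry-over guarantees monotonicity
        out, best = {}, np.inf
        for g in sorted(gens):
            best = min(best, gens[g])
            out[g] = best
        return out

    def to_json_dict(self) -> dict:
        return {
            "schema_version": 1,
            "best_params": dict(self.best_params),
            "best_value": self.best_value,
            "base_seed": self.base_seed,
            "pass_rate": self.pass_rate,
            "config": self.config,
            "trace": [
                {
                    "params": r.params,
                    "value": r.value,
                    "passed": r.passed,
                    "n_ssa_runs": r.n_ssa_runs,
                    "index": r.index,
                    "generation": r.generation,
                }
                for r in self.trace
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2)


def _eval_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, 0x5EED, index]).generate_state(1, np.uint32)[0])


def _prepare(network, data, modes, cfg):
    cfg = cfg or FcondConfig()
    data_pdfs = distributions_from_events(data)
    if modes is None:
        modes = find_modes(
            data_pdfs,
            min_prominence=cfg.mode_min_prominence,
            min_separation_bins=cfg.mode_min_separation_bins,
        )
    return cfg, data_pdfs, modes


def random_search(
    network: ReactionNetwork,
    space: ParameterSpace,
    data: EventTable,
    n_iter: int,
    cfg: FcondConfig | None = None,
    seed: int = 0,
    modes: ModeSet | Sequence[float] | None = None,
) -> FitResult:
    """Uniform random search over the box space (global strategy).

    ``n_iter`` independent uniform draws within bounds (fixed parameters
    held constant), each scored by the conditional objective; returns the
    best-so-far minimum.  Modes are found from the data's final-time
    distribution unless supplied.
    """
    if n_iter < 1:
        raise OptimizerConfigError("n_iter must be >= 1")
    cfg, data_pdfs, modes = _prepare(network, data, modes, cfg)
    rng = np.random.default_rng(seed)
    trace: list[EvalRecord] = []
    best_value, best_params = np.inf, None
    for i in range(n_iter):
        theta = space.sample(rng)
        value, pre, diag = objective_Fcond(
            network, theta, data, modes, cfg, seed=_eval_seed(seed, i), data_pdfs=data_pdfs
        )
        trace.append(EvalRecord(dict(theta), value, pre.passed, diag["n_ssa_runs"], i))
        if value < best_value:
            best_value, best_params = value, theta
    return FitResult(
        best_params=best_params,
        best_value=best_value,
        trace=trace,
        base_seed=seed,
        config={"method": "random_search", "n_iter": n_iter, "ns": cfg.ns},
    )


def _crossover_mutate(parents: list[dict], space: ParameterSpace, mutation: float, rng) -> ParameterSet:
    names = space.free_names
    pa, pb = rng.choice(len(parents), size=2, replace=True)
    child = dict(space.fixed)
    for name in names:
        child[name] = parents[pa][name] if rng.random() < 0.5 else parents[pb][name]
        if rng.random() < mutation:
            lo, hi = space.bounds[name]
            child[name] = rng.uniform(lo, hi)
    return ParameterSet(child)


def genetic_algorithm(
    network: ReactionNetwork,
    space: ParameterSpace,
    data: EventTable,
    ga: GAConfig | None = None,
    cfg: FcondConfig | None = None,
    seed: int = 0,
    modes: ModeSet | Sequence[float] | None = None,
) -> FitResult:
    """Elitist genetic algorithm with adaptive population size.

    Generation 0 is sampled uniformly at ``initial_population`` size; each
    later generation has ``population`` individuals built from the top
    ``ceil(elitism * population)`` ranked individuals of the previous
    generation (ties broken by evaluation order) via uniform per-gene
    crossover of random parent pairs and per-gene uniform-resample
    mutation.  The best individual is carried over unchanged, so the best
    objective value per generation is non-increasing.  Penalized
    individuals can only become parents when fewer passing ones exist than
    parent slots.
    """
    ga = ga or GAConfig()
    cfg, data_pdfs, modes = _prepare(network, data, modes, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6A]))
    trace: list[EvalRecord] = []
    counter = 0

    def evaluate(theta: ParameterSet, generation: int) -> float:
        nonlocal counter
        value, pre, diag = objective_Fcond(
            network, theta, data, modes, cfg, seed=_eval_seed(seed, counter), data_pdfs=data_pdfs
        )
        trace.append(
            EvalRecord(dict(theta), value, pre.passed, diag["n_ssa_runs"], counter, generation)
        )
        counter += 1
        return value

    population = [space.sample(rng) for _ in range(ga.initial_population)]
    values = [evaluate(theta, 0) for theta in population]
    generation_best = [min(values)]

    n_parents = ceil(ga.elitism * ga.population)
    for gen in range(1, ga.generations + 1):
        order = sorted(range(len(population)), key=lambda i: (values[i], i))
        parents = [dict(population[i]) for i in order[:n_parents]]
        best_idx = order[0]
        next_pop = [population[best_idx]]  # elitist carry-over
        next_val = [values[best_idx]]
        while len(next_pop) < ga.population:
            child = _crossover_mutate(parents, space, ga.mutation, rng)
            next_pop.append(child)
            next_val.append(evaluate(child, gen))
        population, values = next_pop, next_val
        generation_best.append(min(values))

    best_i = min(range(len(trace)), key=lambda i: (trace[i].value, i))
    best = trace[best_i]
    return FitResult(
        best_params=ParameterSet(best.params),
        best_value=best.value,
        trace=trace,
        base_seed=seed,
        config={
            "method": "genetic_algorithm",
            "initial_population": ga.initial_population,
            "population": ga.population,
            "generations": ga.generations,
            "elitism": ga.elitism,
            "mutation": ga.mutation,
            "ns": cfg.ns,
        },
        generation_best=generation_best,
    )
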