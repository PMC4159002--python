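"""Evolutionary optimization of replication rate without interactions.

This is the null model against which the evolved master sequence is
compared: an elitist genetic algorithm maximizing the replication-rate
proxy of a genotype, with no ecology at all.  Two structural constraints
are supported: *both_catalytic* (both strands must fold into the catalytic
structure) and *single_catalytic* (exactly the plus strand may be
catalytic).  Infeasible genotypes have fitness 0; inside tournaments,
candidates are additionally ranked by how many of the constraint's strand
requirements they meet, which lets the search climb from a random start
where catalytic folds are rare.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import DEFAULT_ENERGY, EnergyParams
from .folding import FoldEngine
from .phenotype import Genotype, genotype_of
from .seq import random_sequence
from .spectrum import replication_rate_proxy

_BASES = "ACGU"


@dataclass(frozen=True)
class OptimizerParams:
    population_size: int = 100
    generations: int = 400
    mutation_rate: float = 0.01      # per base, per offspring
    tournament_size: int = 3
    constraint: str = "both_catalytic"   # or "single_catalytic"
    seq_length: int = 50
    elite: int = 1
    patience: int = 100              # stop after this many stagnant generations
    polish: bool = True              # exhaustive single-mutant hill climb at the end
    restarts: int = 2                # independent runs; the best result is kept
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")
        if self.constraint not in ("both_catalytic", "single_catalytic"):
            raise ValueError("constraint must be both_catalytic or single_catalytic")


@dataclass
class OptimizeResult:
    best: Genotype
    best_fitness: float
    trajectory: list      # per-generation best fitness (0 while infeasible)
    generations_run: int


def _feasibility(g: Genotype, constraint: str) -> int:
    """Requirements met (3 = fully feasible): the structural constraint on
    each strand, plus viability (3' tails on both strands) — a genotype
    that cannot be replicated has no replication rate to optimize."""
    if constraint == "both_catalytic":
        score = int(g.plus.catalytic) + int(g.minus.catalytic)
    else:
        score = int(g.plus.catalytic) + int(not g.minus.catalytic)
    return score + int(g.plus.has3 and g.minus.has3)


_FEASIBLE = 3


def _fitness(g: Genotype, constraint: str, params: EnergyParams) -> float:
    if _feasibility(g, constraint) < _FEASIBLE:
        return 0.0
    return replication_rate_proxy(g, params)


def _soft_binding(g: Genotype, params: EnergyParams) -> float:
    """Binding quality of the dangling ends with no structural gates:
    breaks ties on the zero-fitness plateaus (e.g. a feasible genotype
    whose 5' tails are still too weak to count), giving selection a
    gradient toward longer, better-matched tails."""
    from .energy import binding_probability, gmin

    best = 0.0
    for c, t in ((g.plus, g.minus), (g.minus, g.plus)):
        if not c.tail5:
            continue
        p_self = binding_probability(gmin(c.tail5, c.tail3, params))
        p_comp = binding_probability(gmin(c.tail5, t.tail3, params))
        best = max(best, 0.5 * (p_self + p_comp))
    return best


def _mutate(seq: str, rate: float, rng) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    if hits.size == 0:
        # a clone explores nothing; force at least one substitution
        hits = rng.integers(len(out), size=1)
    for i in hits:
        out[i] = _BASES.replace(out[i], "")[rng.integers(3)]
    return "".join(out)


def optimize(params: OptimizerParams, engine: FoldEngine,
             energy: EnergyParams = DEFAULT_ENERGY) -> OptimizeResult:
    """Elitist GA over plus-strand sequences, with independent restarts.

    Selection is by tournament on the key (requirements met, fitness, soft
    binding quality); the best individual is carried over unchanged each
    generation, so the best-fitness trajectory is non-decreasing.  Each
    restart stops at ``generations`` or after ``patience`` generations
    without improvement once feasible, then hill-climbs over all single
    substitutions; the best restart is returned.
    """
    seeds = np.random.SeedSequence(params.seed).spawn(max(1, params.restarts))
    results = [_run_once(params, engine, energy, np.random.default_rng(s))
               for s in seeds]
    return max(results, key=lambda r: (_feasibility(r.best, params.constraint),
                                       r.best_fitness))


def _run_once(params: OptimizerParams, engine: FoldEngine,
              energy: EnergyParams, rng) -> OptimizeResult:
    pop = [random_sequence(params.seq_length, rng)
           for _ in range(params.population_size)]

    def evaluate(seq):
        g = genotype_of(seq, engine, energy)
        return (g, _feasibility(g, params.constraint),
                _fitness(g, params.constraint, energy),
                _soft_binding(g, energy))

    key = lambda t: (t[1], t[2], t[3])
    scored = [evaluate(s) for s in pop]
    trajectory = []
    best = max(scored, key=key)
    stagnant = 0
    gens = 0
    for gens in range(1, params.generations + 1):
        new_pop = [best[0].plus.sequence] * params.elite
        while len(new_pop) < params.population_size:
            idx = rng.integers(len(scored), size=params.tournament_size)
            winner = max((scored[i] for i in idx), key=key)
            new_pop.append(_mutate(winner[0].plus.sequence,
                                   params.mutation_rate, rng))
        scored = [evaluate(s) for s in new_pop]
        gen_best = max(scored, key=key)
        if key(gen_best) > key(best):
            if gen_best[2] > best[2] or gen_best[1] > best[1]:
                stagnant = 0
            best = gen_best
        else:
            stagnant += 1
        trajectory.append(best[2])
        if best[1] == _FEASIBLE and stagnant >= params.patience:
            break
    best_g, best_feas, best_fit = best[0], best[1], best[2]
    if params.polish and best_feas == _FEASIBLE:
        best_g, best_fit = _hill_climb(best_g, best_fit, params, engine, energy)
        trajectory.append(best_fit)
    return OptimizeResult(best=best_g, best_fitness=best_fit,
                          trajectory=trajectory, generations_run=gens)


def _hill_climb(g: Genotype, fit: float, params: OptimizerParams, engine,
                energy) -> tuple:
    """Steepest-ascent sweep over all single-substitution mutants, repeated
    until no mutant improves the (feasible) fitness: guarantees the result
    is a local optimum of the single-substitution landscape."""
    improved = True
    while improved:
        improved = False
        seq = g.plus.sequence
        for i, b in enumerate(seq):
            for alt in _BASES:
                if alt == b:
                    continue
                cand = genotype_of(seq[:i] + alt + seq[i + 1:], engine, energy)
                cand_fit = _fitness(cand, params.constraint, energy)
                if cand_fit > fit:
                    g, fit = cand, cand_fit
                    improved = True
        # restart the sweep from the improved sequence
    return g, fit
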