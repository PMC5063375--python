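"""Nested hybrid differential evolution over enzyme-target subsets.

The outer search evolves integer-coded candidate subsets of regulable targets
with differential-evolution operators (rounded difference mutation with
reflection, binomial crossover, duplicate repair), a two-step selection
(one-to-one parent/trial competition, then global-best update), a migration
operator that re-seeds the population when diversity collapses, and an
acceleration step (1-swap hill climb on the incumbent).  Every candidate
subset is evaluated by the inner continuous solve, and the fitness is the
target-count factor times the achieved lambda.  Subset evaluations are
memoized, and per-subset inner seeds are derived from (run seed, subset), so
results are independent of evaluation order and reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .inner import DecisionProblem, DesignPoint, solve_fixed_targets
from .membership import target_count_factor

__all__ = [
    "NHDEConfig",
    "Individual",
    "SearchResult",
    "nhde_search",
    "fixed_cardinality_sweep",
    "combination_search",
    "enumerate_subsets",
]

EMPTY = -1  # sentinel slot value in free-cardinality codes


@dataclass
class NHDEConfig:
    """Hyperparameters of the outer evolutionary search (artifact choices)."""

    population_size: int = 20
    mutation_factor: float = 0.5
    crossover_rate: float = 0.8
    max_generations: int = 200
    migration_threshold: float = 0.1
    acceleration_steps: int = 1
    cardinality: int | None = None  # None: free, <= Z_UB; int: fixed K
    n_starts_inner: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population must have at least 4 individuals")
        if not 0.0 < self.crossover_rate <= 1.0:
            raise ValueError("crossover rate must be in (0, 1]")


@dataclass
class Individual:
    code: np.ndarray  # slot values: target indices or EMPTY
    fitness: float = -1.0
    design: DesignPoint | None = None

    def subset(self) -> tuple[int, ...]:
        vals = sorted(int(c) for c in self.code if c != EMPTY)
        return tuple(dict.fromkeys(vals))


@dataclass
class SearchResult:
    best: DesignPoint
    best_fitness: float
    archive: dict[tuple[str, ...], dict] = field(default_factory=dict)
    history: list[dict] = field(default_factory=list)
    n_evaluations: int = 0


def _subset_seed(run_seed: int, names: tuple[str, ...]) -> int:
    """Deterministic inner-NLP seed from (run seed, subset), order-free."""
    h = hashlib.sha256(("|".join(names) + f"#{run_seed}").encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


class _Evaluator:
    """Memoizing bridge from integer subsets to inner-NLP evaluations."""

    def __init__(self, problem: DecisionProblem, free_names: list[str],
                 preset: tuple[str, ...], run_seed: int, n_starts: int):
        self.problem = problem
        self.free_names = free_names
        self.preset = preset
        self.run_seed = run_seed
        self.n_starts = n_starts
        self.cache: dict[tuple[int, ...], tuple[float, DesignPoint]] = {}
        self.n_evaluations = 0

    def names_of(self, subset: tuple[int, ...]) -> tuple[str, ...]:
        return self.preset + tuple(self.free_names[i] for i in subset)

    def __call__(self, subset: tuple[int, ...]) -> tuple[float, DesignPoint]:
        key = tuple(sorted(subset))
        if key in self.cache:
            return self.cache[key]
        names = self.names_of(key)
        if not names or len(names) > self.problem.sets.z_ub:
            result = (0.0, None)
        else:
            dp = solve_fixed_targets(
                self.problem,
                names,
                n_starts=self.n_starts,
                seed=_subset_seed(self.run_seed, names),
            )
            fitness = target_count_factor(len(names), self.problem.sets.z_ub) * dp.lam
            result = (fitness, dp)
            self.n_evaluations += 1
        self.cache[key] = result
        return result


def _repair(code: np.ndarray, n_free: int, fixed_k: int | None,
            rng: np.random.Generator) -> np.ndarray:
    """Clip slots into range and redraw duplicates."""
    code = code.astype(int)
    lo = 0 if fixed_k is not None else EMPTY
    code = np.clip(code, lo, n_free - 1)
    seen: set[int] = set()
    for i, c in enumerate(code):
        if c == EMPTY:
            continue
        if c in seen:
            choices = [x for x in range(n_free) if x not in seen]
            if choices:
                code[i] = int(rng.choice(choices))
                seen.add(int(code[i]))
            else:
                code[i] = EMPTY
        else:
            seen.add(int(c))
    if fixed_k is not None and (code == EMPTY).any():
        choices = [x for x in range(n_free) if x not in seen]
        for i in np.where(code == EMPTY)[0]:
            if not choices:
                break
            pick = int(rng.choice(choices))
            code[i] = pick
            choices.remove(pick)
    return code


def _random_code(n_slots: int, n_free: int, fixed_k: int | None,
                 rng: np.random.Generator) -> np.ndarray:
    if fixed_k is not None:
        k = min(fixed_k, n_free)
        return np.array(sorted(rng.choice(n_free, size=k, replace=False)), dtype=int)
    code = np.full(n_slots, EMPTY, dtype=int)
    k = int(rng.integers(1, n_slots + 1))
    k = min(k, n_free)
    picks = rng.choice(n_free, size=k, replace=False)
    code[:k] = sorted(int(p) for p in picks)
    return code


def _better(f_a: float, ind_a: Individual, f_b: float, ind_b: Individual) -> bool:
    """Is a better than b?  Ties toward fewer targets, then lexicographic code."""
    if f_a != f_b:
        return f_a > f_b
    ka, kb = len(ind_a.subset()), len(ind_b.subset())
    if ka != kb:
        return ka < kb
    return ind_a.subset() < ind_b.subset()


def nhde_search(
    problem: DecisionProblem,
    config: NHDEConfig | None = None,
    *,
    preset_targets=(),
    progress=None,
) -> SearchResult:
    """Evolve target subsets; return the best design found plus an archive.

    ``preset_targets`` are forced into every candidate (combination mode);
    the evolutionary slots search only the complementary targets.  The best
    fitness is non-decreasing across generations (elitism), and a fixed seed
    yields an identical trajectory.
    """
    config = config or NHDEConfig()
    preset = tuple(preset_targets)
    free_names = [t for t in problem.regulable_targets if t not in preset]
    if not free_names and not preset:
        raise ValueError("no regulable targets")
    rng = np.random.default_rng(config.seed)

    fixed_k = config.cardinality
    n_slots = fixed_k if fixed_k is not None else max(
        problem.sets.z_ub - len(preset), 1
    )
    n_slots = min(n_slots, len(free_names)) if free_names else 0
    evaluate = _Evaluator(
        problem, free_names, preset, config.seed, config.n_starts_inner
    )

    if n_slots == 0:
        # nothing free to search: degenerate to evaluating the preset alone
        fitness, dp = evaluate(())
        return SearchResult(
            best=dp,
            best_fitness=fitness,
            archive={evaluate.names_of(()): {"fitness": fitness, "lambda": dp.lam}},
            n_evaluations=evaluate.n_evaluations,
        )

    pop = [
        Individual(_random_code(n_slots, len(free_names), fixed_k, rng))
        for _ in range(config.population_size)
    ]
    if preset and fixed_k is None:
        # the preset alone is a valid candidate; make sure it is in the pool
        pop[0] = Individual(np.full(n_slots, EMPTY, dtype=int))
    for ind in pop:
        ind.fitness, ind.design = evaluate(ind.subset())
    best = max(pop, key=lambda i: (i.fitness, -len(i.subset())))
    best = Individual(best.code.copy(), best.fitness, best.design)

    history = []
    for gen in range(config.max_generations):
        for i, parent in enumerate(pop):
            r = rng.choice([j for j in range(len(pop)) if j != i], size=3, replace=False)
            a, b, c = (pop[int(j)].code for j in r)
            mutant = np.rint(a + config.mutation_factor * (b - c)).astype(int)
            # reflect out-of-range slots back into the valid window
            lo = 0 if fixed_k is not None else EMPTY
            hi = len(free_names) - 1
            span = hi - lo
            if span > 0:
                mutant = np.where(mutant < lo, lo + (lo - mutant) % (span + 1), mutant)
                mutant = np.where(mutant > hi, hi - (mutant - hi) % (span + 1), mutant)
            # binomial crossover with a guaranteed slot from the mutant
            cross = rng.random(n_slots) < config.crossover_rate
            cross[int(rng.integers(0, n_slots))] = True
            trial_code = np.where(cross, mutant, parent.code)
            trial_code = _repair(trial_code, len(free_names), fixed_k, rng)
            trial = Individual(trial_code)
            if not trial.subset() and not preset:
                continue
            trial.fitness, trial.design = evaluate(trial.subset())
            # selection step 1: one-to-one competition
            if _better(trial.fitness, trial, parent.fitness, parent):
                pop[i] = trial
            # selection step 2: global best update
            if _better(pop[i].fitness, pop[i], best.fitness, best):
                best = Individual(pop[i].code.copy(), pop[i].fitness, pop[i].design)

        # acceleration: 1-swap hill climb on the incumbent
        for _ in range(config.acceleration_steps):
            improved = False
            subset = best.subset()
            if not subset:
                break
            slots = list(subset)
            order = rng.permutation(len(slots))
            for pos in order:
                current = slots[int(pos)]
                candidates = [x for x in range(len(free_names)) if x not in subset]
                if not candidates:
                    continue
                swap = int(rng.choice(candidates))
                cand_subset = tuple(sorted(set(slots) - {current} | {swap}))
                f, dp = evaluate(cand_subset)
                cand = Individual(np.array(cand_subset, dtype=int), f, dp)
                if _better(f, cand, best.fitness, best):
                    code = np.full_like(best.code, EMPTY)
                    code[: len(cand_subset)] = cand_subset
                    best = Individual(code, f, dp)
                    improved = True
                    break
            if not improved:
                break

        diversity = len({ind.subset() for ind in pop}) / len(pop)
        history.append(
            {"generation": gen, "best_fitness": best.fitness, "diversity": diversity}
        )
        if progress is not None:
            progress(history[-1])
        # migration: re-seed all but the best when diversity collapses
        if diversity < config.migration_threshold:
            keep = best
            pop = [Individual(keep.code.copy(), keep.fitness, keep.design)]
            while len(pop) < config.population_size:
                ind = Individual(
                    _random_code(n_slots, len(free_names), fixed_k, rng)
                )
                ind.fitness, ind.design = evaluate(ind.subset())
                pop.append(ind)

    archive = {
        evaluate.names_of(k): {
            "fitness": f,
            "lambda": dp.lam if dp else 0.0,
            "T": dp.report.T if dp else 0.0,
            "A": dp.report.A if dp else 0.0,
            "V": dp.report.V if dp else 0.0,
        }
        for k, (f, dp) in evaluate.cache.items()
    }
    return SearchResult(
        best=best.design,
        best_fitness=best.fitness,
        archive=archive,
        history=history,
        n_evaluations=evaluate.n_evaluations,
    )


def fixed_cardinality_sweep(
    problem: DecisionProblem, k_list, config: NHDEConfig | None = None
) -> dict[int, SearchResult]:
    """One search per fixed target count K; report table mirrors the per-K
    comparison of the case study."""
    config = config or NHDEConfig()
    out = {}
    for k in k_list:
        if k > len(problem.regulable_targets):
            raise ValueError(f"K={k} exceeds the number of regulable targets")
        cfg = NHDEConfig(
            population_size=config.population_size,
            mutation_factor=config.mutation_factor,
            crossover_rate=config.crossover_rate,
            max_generations=config.max_generations,
            migration_threshold=config.migration_threshold,
            acceleration_steps=config.acceleration_steps,
            cardinality=int(k),
            n_starts_inner=config.n_starts_inner,
            seed=config.seed + int(k),
        )
        out[int(k)] = nhde_search(problem, cfg)
    return out


def combination_search(
    problem: DecisionProblem, preset_targets, config: NHDEConfig | None = None
) -> SearchResult:
    """Search complementary targets around a forced treatment preset."""
    return nhde_search(problem, config, preset_targets=tuple(preset_targets))


def enumerate_subsets(
    problem: DecisionProblem, max_k: int = 1, *, seed: int = 0, n_starts: int = 8
) -> tuple[DesignPoint, float, dict]:
    """Exhaustive oracle: evaluate every subset of size 1..max_k.

    Used by tests as the independent reference for the evolutionary search.
    Returns (best design, best fitness, archive keyed by subset names).
    """
    from itertools import combinations

    names = problem.regulable_targets
    best_dp, best_fit, best_key = None, -1.0, None
    archive = {}
    for k in range(1, max_k + 1):
        for combo in combinations(names, k):
            dp = solve_fixed_targets(
                problem, combo, n_starts=n_starts, seed=_subset_seed(seed, combo)
            )
            fit = target_count_factor(k, problem.sets.z_ub) * dp.lam
            archive[combo] = fit
            if fit > best_fit or (
                fit == best_fit and best_key is not None and (
                    len(combo) < len(best_key) or
                    (len(combo) == len(best_key) and combo < best_key)
                )
            ):
                best_dp, best_fit, best_key = dp, fit, combo
    return best_dp, best_fit, archive
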