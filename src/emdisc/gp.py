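"""Strongly-typed genetic programming over farm-selection rules.

Evolves :class:`~emdisc.rules.RuleTree` individuals against simulator RMSE.
Individuals carry one connectivity configuration and an expression tree over
the nine factor terminals and the ``+``/``-`` operators; every tree ever
constructed satisfies the type-compatibility condition (children are admitted
only where their return type matches the parent's parameter type) and the
configured depth bounds.

Protocol per run: ramped half-and-half initialization, tournament selection,
typed one-point subtree crossover, typed subtree-regrow mutation, and an
elitist hall of fame of size one. Every fitness evaluation redraws the
simulator's demographic parameters uniformly from their +/-5% windows before
running a single seeded simulation, so fitness reflects robustness to
parameter uncertainty and memoization is deliberately absent. Evaluations are
independent tasks whose RNG streams derive from ``(seed, run, generation,
index)``; a parallel executor therefore reproduces the serial results
exactly.

Every evaluation across all runs is appended to the factor-scores table
(presence coefficients, connectivity, fitness, run, generation), the input to
the downstream random-forest importance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .abm import DEFAULT_PARAM_RANGES, InitConfig, draw_params, run_simulation
from .landscape import Landscape
from .rules import (
    CONNECTIVITIES,
    FACTORS,
    BinOp,
    FactorConfig,
    Node,
    RuleTree,
    SCORE,
    SIGNATURES,
    Terminal,
    check_types,
    extract_presence,
    node_depth,
)

__all__ = [
    "GPConfig",
    "EvaluatedRule",
    "init_population",
    "evaluate_fitness",
    "evolve",
    "TABLE_COLUMNS",
]

TABLE_COLUMNS = list(FACTORS) + ["connectivity", "fitness", "run", "generation"]

_TERMINALS = [name for name, sig in SIGNATURES.items() if sig.arity == 0]
_OPERATORS = [name for name, sig in SIGNATURES.items() if sig.arity > 0]


@dataclass(frozen=True)
class GPConfig:
    """Search configuration. Defaults follow the full-scale protocol
    (20 runs x 100 generations x 50 individuals, tree depths 4-10)."""

    population_size: int = 50
    generations: int = 100
    min_depth: int = 4
    max_depth: int = 10
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    connectivity_mutation_prob: float = 0.1
    tournament_size: int = 3
    n_runs: int = 20
    seed: int = 0
    param_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_RANGES))
    init: InitConfig = field(default_factory=InitConfig)
    factor_config: FactorConfig = field(default_factory=FactorConfig)
    n_jobs: int = 1

    def __post_init__(self):
        if not (0 <= self.min_depth <= self.max_depth):
            raise ValueError("need 0 <= min_depth <= max_depth")
        for p in (self.crossover_prob, self.mutation_prob, self.connectivity_mutation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class EvaluatedRule:
    """One fitness evaluation: the rule, its presence and the simulated RMSE."""

    rule: RuleTree
    presence: dict[str, int]
    fitness: float
    run_id: int
    generation: int
    seed: tuple[int, ...]
    params: "object"


# ---------------------------------------------------------------------------
# Tree generation
# ---------------------------------------------------------------------------

def _gen_tree(rng: np.random.Generator, target_depth: int, full: bool,
              return_type: str = SCORE) -> Node:
    """Grow one typed subtree of depth <= ``target_depth``.

    ``full=True`` places operators at every level above ``target_depth``;
    otherwise terminals may appear early (classic "grow"). Candidate
    primitives are filtered by return type, so the result is well typed by
    construction.
    """
    terminals = [t for t in _TERMINALS if SIGNATURES[t].return_type == return_type]
    operators = [o for o in _OPERATORS if SIGNATURES[o].return_type == return_type]
    if target_depth <= 0 or not operators:
        return Terminal(terminals[rng.integers(len(terminals))])
    use_op = True if full else rng.random() < 0.7
    if not use_op:
        return Terminal(terminals[rng.integers(len(terminals))])
    op = operators[rng.integers(len(operators))]
    sig = SIGNATURES[op]
    children = [
        _gen_tree(rng, target_depth - 1, full, return_type=pt) for pt in sig.param_types
    ]
    return BinOp(op, children[0], children[1])


def _random_tree(rng: np.random.Generator, min_depth: int, max_depth: int, full: bool) -> Node:
    """Half-and-half building block: one tree with depth in [min, max]."""
    target = int(rng.integers(min_depth, max_depth + 1))
    for _ in range(100):
        tree = _gen_tree(rng, target, full)
        if min_depth <= node_depth(tree) <= max_depth:
            return tree
    # Fall back to a full tree, which always hits the target depth exactly.
    return _gen_tree(rng, target, True)


def init_population(config: GPConfig, rng: np.random.Generator) -> list[RuleTree]:
    """Ramped half-and-half population: half full trees, half grown trees."""
    pop = []
    for i in range(config.population_size):
        full = i % 2 == 0
        root = _random_tree(rng, config.min_depth, config.max_depth, full)
        conn = CONNECTIVITIES[rng.integers(len(CONNECTIVITIES))]
        pop.append(RuleTree(conn, root))
    return pop


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def _collect_subtrees(node: Node, path=()) -> list[tuple[tuple, Node]]:
    out = [(path, node)]
    if isinstance(node, BinOp):
        out += _collect_subtrees(node.left, path + (0,))
        out += _collect_subtrees(node.right, path + (1,))
    return out


def _replace_at(node: Node, path: tuple, sub: Node) -> Node:
    if not path:
        return sub
    if path[0] == 0:
        return BinOp(node.op, _replace_at(node.left, path[1:], sub), node.right)
    return BinOp(node.op, node.left, _replace_at(node.right, path[1:], sub))


def _subtree_at(node: Node, path: tuple) -> Node:
    for p in path:
        node = node.left if p == 0 else node.right
    return node


def _crossover(a: RuleTree, b: RuleTree, config: GPConfig, rng: np.random.Generator):
    """Typed one-point crossover; depth-violating offspring revert to parents."""
    subs_a = _collect_subtrees(a.root)
    subs_b = _collect_subtrees(b.root)
    pa, sa = subs_a[rng.integers(len(subs_a))]
    # Only type-compatible donor subtrees may fill the chosen slot.
    want = check_types(sa)
    compatible = [(p, s) for p, s in subs_b if check_types(s) == want]
    pb, sb = compatible[rng.integers(len(compatible))]
    child_a = replace(a, root=_replace_at(a.root, pa, sb))
    child_b = replace(b, root=_replace_at(b.root, pb, sa))
    if not (config.min_depth <= child_a.depth <= config.max_depth):
        child_a = a
    if not (config.min_depth <= child_b.depth <= config.max_depth):
        child_b = b
    return child_a, child_b


def _mutate(ind: RuleTree, config: GPConfig, rng: np.random.Generator) -> RuleTree:
    """Regrow a random subtree; revert if the result violates depth bounds."""
    subs = _collect_subtrees(ind.root)
    path, old = subs[rng.integers(len(subs))]
    budget = config.max_depth - len(path)
    sub = _gen_tree(rng, int(rng.integers(0, budget + 1)), full=False,
                    return_type=check_types(old))
    child = replace(ind, root=_replace_at(ind.root, path, sub))
    if not (config.min_depth <= child.depth <= config.max_depth):
        return ind
    return child


def _mutate_connectivity(ind: RuleTree, rng: np.random.Generator) -> RuleTree:
    options = [c for c in CONNECTIVITIES if c != ind.connectivity]
    return replace(ind, connectivity=options[rng.integers(len(options))])


def _tournament(fits: list[float], k: int, rng: np.random.Generator) -> int:
    contenders = rng.integers(0, len(fits), size=k)
    return int(min(contenders, key=lambda i: fits[i]))


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def evaluate_fitness(
    rule: RuleTree,
    landscape: Landscape,
    config: GPConfig,
    rng_key: tuple[int, int, int, int],
) -> EvaluatedRule:
    """Draw parameters from their windows, run one simulation, record RMSE.

    ``rng_key = (seed, run, generation, index)`` fully determines the
    parameter draw and the simulation stream.
    """
    rng = np.random.default_rng(list(rng_key))
    params = draw_params(config.param_ranges, rng)
    try:
        result = run_simulation(
            landscape, params, rule, init=config.init, rng=rng,
            factor_config=config.factor_config,
        )
    except Exception as exc:  # pragma: no cover - defensive context attachment
        raise RuntimeError(f"simulation failed for rule {rule}: {exc}") from exc
    return EvaluatedRule(
        rule=rule,
        presence=extract_presence(rule),
        fitness=result.rmse,
        run_id=rng_key[1],
        generation=rng_key[2],
        seed=rng_key,
        params=params,
    )


def _assert_valid(ind: RuleTree, config: GPConfig) -> None:
    assert check_types(ind.root) == SCORE
    assert config.min_depth <= ind.depth <= config.max_depth, (
        f"depth {ind.depth} outside [{config.min_depth}, {config.max_depth}]"
    )


def _evaluate_batch(pop, landscape, config, run, gen) -> list[EvaluatedRule]:
    keys = [(config.seed, run, gen, i) for i in range(len(pop))]
    if config.n_jobs == 1:
        return [evaluate_fitness(ind, landscape, config, k) for ind, k in zip(pop, keys)]
    return Parallel(n_jobs=config.n_jobs)(
        delayed(evaluate_fitness)(ind, landscape, config, k) for ind, k in zip(pop, keys)
    )


def evolve(config: GPConfig, landscape: Landscape) -> tuple[list[EvaluatedRule], pd.DataFrame]:
    """Run ``config.n_runs`` independent GP runs.

    Returns the hall-of-fame best evaluation of each run and the concatenated
    factor-scores table with one row per fitness evaluation performed
    (``population_size * (generations + 1)`` rows per run).
    """
    best_per_run: list[EvaluatedRule] = []
    rows: list[tuple] = []

    for run in range(config.n_runs):
        rng = np.random.default_rng([config.seed, run])
        pop = init_population(config, rng)
        for ind in pop:
            _assert_valid(ind, config)
        evals = _evaluate_batch(pop, landscape, config, run, gen=0)
        _record(rows, evals)
        hof = min(evals, key=lambda e: e.fitness)

        for gen in range(1, config.generations + 1):
            fits = [e.fitness for e in evals]
            selected = [pop[_tournament(fits, config.tournament_size, rng)]
                        for _ in range(config.population_size)]
            offspring = list(selected)
            for i in range(0, len(offspring) - 1, 2):
                if rng.random() < config.crossover_prob:
                    offspring[i], offspring[i + 1] = _crossover(
                        offspring[i], offspring[i + 1], config, rng
                    )
            for i in range(len(offspring)):
                if rng.random() < config.mutation_prob:
                    offspring[i] = _mutate(offspring[i], config, rng)
                if rng.random() < config.connectivity_mutation_prob:
                    offspring[i] = _mutate_connectivity(offspring[i], rng)
                _assert_valid(offspring[i], config)
            pop = offspring
            evals = _evaluate_batch(pop, landscape, config, run, gen)
            _record(rows, evals)
            gen_best = min(evals, key=lambda e: e.fitness)
            if gen_best.fitness < hof.fitness:
                hof = gen_best
        best_per_run.append(hof)

    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    return best_per_run, table


def _record(rows: list, evals: list[EvaluatedRule]) -> None:
    for e in evals:
        assert np.isfinite(e.fitness) and e.fitness >= 0
        rows.append(
            tuple(e.presence[f] for f in FACTORS)
            + (e.rule.connectivity, e.fitness, e.run_id, e.generation)
        )
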