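"""Annual-step household demographic simulator with pluggable farm selection.

Each simulated year proceeds, in order:

1. every household harvests its farm:
   ``yield = baseline_yield(zone, year) * quality * harvest_adjustment * max(0, 1 + eps)``
   with ``eps ~ Normal(0, harvest_variance)`` (the multiplier is floored at
   zero so harvests stay non-negative);
2. each household consumes its annual nutrition need from the oldest maize
   vintage first, then discards vintages older than two years;
3. households older than their individually drawn death age are removed;
4. households whose estimated next-year harvest (the current year's realized
   harvest) falls short of their need invoke the farm-selection strategy on
   the candidate plots admitted by the rule's connectivity configuration and
   re-site their dwelling within ``water_source_distance`` of an active water
   source; households with no admissible farm or dwelling leave the valley;
5. households of fertile age whose total corn covers one year's need fission
   with their individual fertility probability; the child receives
   ``maize_gift_to_child`` of the parent's stock and selects its own farm via
   the same strategy, deciding from the parent's location.

Household ages then advance by one year. The order in which households act in
the plot-competition steps (4, 5) is reshuffled every year from the run RNG,
so outcomes carry no household-id ordering artifact. An empty population is a
valid absorbing state. There is no explicit starvation mortality: a household
that cannot feed itself stops fissioning and, via the relocation trigger,
either finds a better farm or leaves when none is admissible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .landscape import Landscape, Occupancy, available_mask
from .rules import (
    DecisionContext,
    FactorConfig,
    RuleTree,
    StepCache,
    candidate_subset,
    evaluate_rule,
    parse_rule,
)

__all__ = [
    "DEFAULT_PARAM_RANGES",
    "SimulationParams",
    "draw_params",
    "Household",
    "SimState",
    "InitConfig",
    "SimulationResult",
    "init_state",
    "step_year",
    "run_simulation",
    "nearest_available_plot",
]

#: +/-5% windows about the calibrated optimum of each demographic parameter.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "water_source_distance": (10.925, 12.075),
    "death_age_span": (9.5, 10.5),
    "min_fertility": (0.1615, 0.1785),
    "base_nutrition_need": (175.75, 194.25),
    "fertility_span": (0.0285, 0.0315),
    "min_fertility_ends_age": (27.55, 30.45),
    "harvest_variance": (0.418, 0.462),
    "harvest_adjustment": (0.608, 0.672),
    "maize_gift_to_child": (0.4465, 0.4935),
    "min_death_age": (38.0, 42.0),
    "fertility_ends_age_span": (4.75, 5.25),
}


@dataclass(frozen=True)
class SimulationParams:
    """Demographic and agricultural parameters.

    Defaults are the midpoints of :data:`DEFAULT_PARAM_RANGES`.
    ``fertility_start_age`` is the fixed lower bound of the fertility window
    and is not part of the randomized windows.
    """

    water_source_distance: float = 11.5
    min_death_age: float = 40.0
    death_age_span: float = 10.0
    min_fertility: float = 0.17
    fertility_span: float = 0.03
    min_fertility_ends_age: float = 29.0
    fertility_ends_age_span: float = 5.0
    base_nutrition_need: float = 185.0
    harvest_adjustment: float = 0.64
    harvest_variance: float = 0.44
    maize_gift_to_child: float = 0.47
    fertility_start_age: float = 16.0

    def __post_init__(self):
        if not (0.0 <= self.min_fertility <= 1.0):
            raise ValueError("min_fertility must lie in [0, 1]")
        if not (0.0 <= self.maize_gift_to_child <= 1.0):
            raise ValueError("maize_gift_to_child must lie in [0, 1]")
        for name in ("death_age_span", "fertility_span", "fertility_ends_age_span", "harvest_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


_PARAM_NAMES = {f.name for f in fields(SimulationParams)}


def draw_params(ranges: dict[str, tuple[float, float]], rng: np.random.Generator) -> SimulationParams:
    """Draw each named parameter uniformly and independently from its window.

    Parameters are drawn in sorted name order so the result depends only on
    the RNG state and the window set, not on dict insertion order.
    """
    values: dict[str, float] = {}
    for name in sorted(ranges):
        if name not in _PARAM_NAMES:
            raise ValueError(f"unknown simulation parameter: {name!r}")
        lo, hi = ranges[name]
        if lo > hi:
            raise ValueError(f"parameter {name!r}: low {lo} > high {hi}")
        values[name] = float(rng.uniform(lo, hi))
    return SimulationParams(**values)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Household:
    """One household agent (identity semantics: compared by object, not value)."""

    id: int
    parent_id: int | None
    age: float
    farm: tuple[int, int]
    dwelling: tuple[int, int]
    corn: dict[int, float]  # harvest year -> kg
    nutrition_need: float
    death_age: float
    fertility_end_age: float
    fertility: float
    last_harvest: float = 0.0

    @property
    def total_corn(self) -> float:
        return sum(self.corn.values())


@dataclass
class StepLedger:
    """Corn mass bookkeeping for one simulated year (kg)."""

    harvested: float = 0.0
    consumed: float = 0.0
    discarded: float = 0.0
    lost_to_removals: float = 0.0


@dataclass
class SimState:
    """Mutable simulation state for one year."""

    year: int
    households: list[Household]
    occupancy: Occupancy
    last_yield: np.ndarray
    next_id: int
    ledger: StepLedger = field(default_factory=StepLedger)
    # Performance caches maintained by step_year (not part of the model state).
    soc_count: np.ndarray | None = field(default=None, repr=False)
    soc_radius: float | None = field(default=None, repr=False)
    water_grids: dict = field(default_factory=dict, repr=False)

    @property
    def count(self) -> int:
        return len(self.households)

    def total_corn(self) -> float:
        return sum(h.total_corn for h in self.households)


@dataclass(frozen=True)
class InitConfig:
    """Initial-population specification.

    ``count=None`` starts from the target series' first value, anchoring the
    year-0 error at zero. Households are placed on the highest-quality
    available plots with dwellings sited near water; initial ages are drawn
    uniformly from ``[age_low, age_high)`` and every household starts with one
    year's nutrition need in storage.
    """

    count: int | None = None
    age_low: int = 0
    age_high: int = 30


@dataclass
class SimulationResult:
    """Household-count trajectory and its RMSE against the target series."""

    counts: dict[int, int]
    rmse: float
    params: SimulationParams

    def to_frame(self, landscape: Landscape) -> pd.DataFrame:
        years = sorted(self.counts)
        return pd.DataFrame(
            {
                "year": years,
                "simulated": [self.counts[y] for y in years],
                "target": [landscape.target(y) for y in years],
            }
        )


# ---------------------------------------------------------------------------
# Strategy plumbing
# ---------------------------------------------------------------------------

def _as_strategy(strategy) -> tuple[str, "object"]:
    """Normalize a strategy argument to (connectivity, selector callable).

    Accepts a :class:`RuleTree`, a canonical rule string, or a bare callable
    ``ctx -> (x, y) | None`` (treated as full-information).
    """
    if isinstance(strategy, str):
        strategy = parse_rule(strategy)
    if isinstance(strategy, RuleTree):
        return strategy.connectivity, lambda ctx: evaluate_rule(strategy, ctx)
    if callable(strategy):
        return "S_All", strategy
    raise TypeError(f"not a strategy: {strategy!r}")


def nearest_available_plot(ctx: DecisionContext) -> tuple[int, int] | None:
    """Reference implementation of the original nearest-plot behaviour.

    Independent of the rule language: scans candidates for the minimum
    Euclidean distance to the reference farm, ties broken on lowest (y, x).
    """
    plots = ctx.candidates
    if plots is None or len(plots) == 0:
        return None
    best = None
    for x, y in plots:
        d = math.hypot(int(x) - ctx.ref_farm[0], int(y) - ctx.ref_farm[1])
        key = (d, int(y), int(x))
        if best is None or key < best:
            best = key
    return best[2], best[1]


# ---------------------------------------------------------------------------
# Mechanics
# ---------------------------------------------------------------------------

def _disc_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer (dx, dy) offsets with dx^2 + dy^2 <= radius^2 (cached)."""
    key = round(float(radius), 6)
    cached = _disc_offsets._cache.get(key)
    if cached is None:
        r = int(np.floor(radius))
        dx, dy = np.mgrid[-r : r + 1, -r : r + 1]
        keep = dx**2 + dy**2 <= radius**2
        cached = _disc_offsets._cache[key] = (dx[keep], dy[keep])
    return cached


_disc_offsets._cache = {}


def _add_disc(grid: np.ndarray, x: int, y: int, radius: float, delta: float) -> None:
    """Add ``delta`` to all cells within ``radius`` of (x, y), clipped to grid."""
    dx, dy = _disc_offsets(radius)
    xs, ys = x + dx, y + dy
    keep = (xs >= 0) & (xs < grid.shape[1]) & (ys >= 0) & (ys < grid.shape[0])
    grid[ys[keep], xs[keep]] += delta


def _step_cache(
    state: "SimState", landscape: Landscape, year: int, cfg: FactorConfig
) -> StepCache:
    """This year's factor grids (identical to the per-decision fallback
    computations in :mod:`emdisc.rules`, just amortized).

    The dwelling-density grid persists on the state and is maintained
    incrementally as dwellings appear, move or vanish; water-source count
    grids are cached per active-source set.
    """
    h, w = landscape.height, landscape.width
    if state.soc_count is None or state.soc_radius != cfg.social_radius:
        soc = np.zeros((h, w))
        for hh in state.households:
            _add_disc(soc, hh.dwelling[0], hh.dwelling[1], cfg.social_radius, 1.0)
        state.soc_count = soc
        state.soc_radius = cfg.social_radius
    active = tuple((s.x, s.y) for s in landscape.active_water_sources(year))
    water = state.water_grids.get((active, cfg.social_radius))
    if water is None:
        water = np.zeros((h, w))
        for x, y in active:
            _add_disc(water, x, y, cfg.social_radius, 1.0)
        state.water_grids[(active, cfg.social_radius)] = water
    dry = -landscape.baseline_yield(landscape.zone, year)
    return StepCache(soc_count=state.soc_count, water_count=water, dry=dry)


def _water_ok_mask(landscape: Landscape, year: int, max_dist: float) -> np.ndarray:
    """Cells within ``max_dist`` of a water source active in ``year``."""
    ok = np.zeros((landscape.height, landscape.width), dtype=bool)
    ys, xs = np.mgrid[0 : landscape.height, 0 : landscape.width]
    for s in landscape.active_water_sources(year):
        ok |= (xs - s.x) ** 2 + (ys - s.y) ** 2 <= max_dist**2
    return ok


def _find_dwelling(
    landscape: Landscape,
    occupancy: Occupancy,
    water_ok: np.ndarray,
    near: tuple[int, int],
) -> tuple[int, int] | None:
    """Nearest available cell to ``near`` that satisfies the water constraint.

    Searches a small window first; a hit at Euclidean distance <= the window
    radius is provably the global optimum, otherwise falls back to the full
    grid.
    """
    ok = available_mask(landscape, occupancy) & water_ok
    x0, y0 = near
    r = 3
    xl, xh = max(0, x0 - r), min(landscape.width, x0 + r + 1)
    yl, yh = max(0, y0 - r), min(landscape.height, y0 + r + 1)
    ys, xs = np.nonzero(ok[yl:yh, xl:xh])
    if len(xs):
        xs, ys = xs + xl, ys + yl
        d2 = (xs - x0) ** 2 + (ys - y0) ** 2
        i = np.lexsort((xs, ys, d2))[0]
        if d2[i] <= r * r:
            return int(xs[i]), int(ys[i])
    ys, xs = np.nonzero(ok)
    if len(xs) == 0:
        return None
    d2 = (xs - x0) ** 2 + (ys - y0) ** 2
    i = np.lexsort((xs, ys, d2))[0]
    return int(xs[i]), int(ys[i])


def _draw_lifecycle(params: SimulationParams, rng: np.random.Generator) -> tuple[float, float, float]:
    death_age = params.min_death_age + rng.uniform(0.0, params.death_age_span)
    fertility_end = params.min_fertility_ends_age + rng.uniform(0.0, params.fertility_ends_age_span)
    fertility = params.min_fertility + rng.uniform(0.0, params.fertility_span)
    return death_age, fertility, fertility_end


def _build_context(
    state: SimState,
    landscape: Landscape,
    factor_config: FactorConfig,
    ref_farm: tuple[int, int],
    ref_dwelling: tuple[int, int],
    ref_age: float,
    ref_stock: float,
    decider: Household | None,
    cache: StepCache | None = None,
    need_family: bool = True,
    need_arrays: bool = True,
) -> DecisionContext:
    hh = state.households
    if need_arrays:
        ids = np.array([h.id for h in hh], dtype=np.int64)
        dwellings = np.array([h.dwelling for h in hh], dtype=np.int64).reshape(-1, 2)
        ages = np.array([h.age for h in hh], dtype=float)
        stocks = np.array([h.total_corn for h in hh], dtype=float)
    else:
        # Lean mode: the caller knows the rule touches no per-household factor
        # (homophily) and the connectivity is full-information.
        ids = _EMPTY_IDS
        dwellings = _EMPTY_XY
        ages = stocks = _EMPTY_F

    family: frozenset[int] = frozenset()
    if decider is not None and need_family:
        by_id = {h.id: h for h in hh}
        fam = {decider.id}
        if decider.parent_id is not None:
            fam.add(decider.parent_id)  # parent (if surviving)
            parent = by_id.get(decider.parent_id)
            if parent is not None and parent.parent_id is not None:
                fam.add(parent.parent_id)  # grandparent
            fam.update(h.id for h in hh if h.parent_id == decider.parent_id)  # siblings
        family = frozenset(fam)

    return DecisionContext(
        landscape=landscape,
        year=state.year,
        ref_farm=ref_farm,
        ref_dwelling=ref_dwelling,
        ref_zone=int(landscape.zone[ref_farm[1], ref_farm[0]]),
        ref_age=ref_age,
        ref_stock=ref_stock,
        decider_id=None if decider is None else decider.id,
        hh_ids=ids,
        hh_dwellings=dwellings,
        hh_ages=ages,
        hh_stocks=stocks,
        family_ids=family,
        available=available_mask(landscape, state.occupancy),
        last_yield=state.last_yield,
        config=factor_config,
        cache=cache,
    )


_EMPTY_IDS = np.empty(0, dtype=np.int64)
_EMPTY_XY = np.empty((0, 2), dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=float)


def _remove(state: SimState, h: Household) -> None:
    state.occupancy.farm[h.farm[1], h.farm[0]] = False
    state.occupancy.dwelling[h.dwelling[1], h.dwelling[0]] = False
    state.ledger.lost_to_removals += h.total_corn
    state.households.remove(h)


def init_state(
    landscape: Landscape,
    params: SimulationParams,
    init: InitConfig,
    rng: np.random.Generator,
) -> SimState:
    """Place the initial population on the best land, dwellings near water."""
    count = init.count if init.count is not None else int(landscape.target_series[0])
    occupancy = Occupancy.empty(landscape.height, landscape.width)
    water_ok = _water_ok_mask(landscape, landscape.start_year, params.water_source_distance)

    q = np.where(landscape.water_body, -np.inf, landscape.quality)
    ys, xs = np.mgrid[0 : landscape.height, 0 : landscape.width]
    order = np.lexsort((xs.ravel(), ys.ravel(), -q.ravel()))

    state = SimState(
        year=landscape.start_year,
        households=[],
        occupancy=occupancy,
        last_yield=np.zeros((landscape.height, landscape.width)),
        next_id=0,
    )
    placed = 0
    for idx in order:
        if placed >= count:
            break
        y, x = int(ys.ravel()[idx]), int(xs.ravel()[idx])
        if not available_mask(landscape, occupancy)[y, x]:
            continue
        occupancy.farm[y, x] = True
        dwelling = _find_dwelling(landscape, occupancy, water_ok, (x, y))
        if dwelling is None:
            occupancy.farm[y, x] = False
            continue
        occupancy.dwelling[dwelling[1], dwelling[0]] = True
        age = float(rng.integers(init.age_low, init.age_high))
        death_age, fertility, fertility_end = _draw_lifecycle(params, rng)
        state.households.append(
            Household(
                id=state.next_id,
                parent_id=None,
                age=age,
                farm=(x, y),
                dwelling=dwelling,
                corn={landscape.start_year - 1: params.base_nutrition_need},
                nutrition_need=params.base_nutrition_need,
                death_age=death_age,
                fertility_end_age=fertility_end,
                fertility=fertility,
            )
        )
        state.next_id += 1
        placed += 1
    if placed < count:
        raise ValueError(f"could only place {placed} of {count} initial households")
    return state


def step_year(
    state: SimState,
    landscape: Landscape,
    params: SimulationParams,
    strategy,
    rng: np.random.Generator,
    factor_config: FactorConfig | None = None,
) -> SimState:
    """Advance the state by one year (mutates and returns ``state``)."""
    factor_config = factor_config or FactorConfig()
    connectivity, select = _as_strategy(strategy)
    year = state.year
    state.ledger = StepLedger()
    water_ok = _water_ok_mask(landscape, year, params.water_source_distance)

    # (1) harvest, in id order
    for h in state.households:
        x, y = h.farm
        base = landscape.baseline_yield(int(landscape.zone[y, x]), year)
        eps = rng.normal(0.0, params.harvest_variance)
        amount = base * landscape.quality[y, x] * params.harvest_adjustment * max(0.0, 1.0 + eps)
        h.corn[year] = h.corn.get(year, 0.0) + amount
        h.last_harvest = amount
        state.last_yield[y, x] = amount
        state.ledger.harvested += amount

    # (2) consume oldest-first, then discard vintages older than 2 years
    for h in state.households:
        need = h.nutrition_need
        for vintage in sorted(h.corn):
            take = min(need, h.corn[vintage])
            h.corn[vintage] -= take
            state.ledger.consumed += take
            need -= take
            if need <= 0:
                break
        for vintage in [v for v in h.corn if v <= year - 2 or h.corn[v] <= 0.0]:
            if vintage <= year - 2:
                state.ledger.discarded += h.corn[vintage]
            del h.corn[vintage]

    cache = _step_cache(state, landscape, year, factor_config)
    alive = set(id(h) for h in state.households)
    need_family = connectivity == "S_Fam"
    if isinstance(strategy, RuleTree) or isinstance(strategy, str):
        tree = strategy if isinstance(strategy, RuleTree) else parse_rule(strategy)
        used = {f for f, k in tree.presence().items() if k != 0}
        need_arrays = connectivity != "S_All" or bool(used & {"HAge", "HAgri"})
    else:
        need_arrays = True

    def drop_dwelling(d: tuple[int, int]) -> None:
        _add_disc(state.soc_count, d[0], d[1], factor_config.social_radius, -1.0)

    def add_dwelling(d: tuple[int, int]) -> None:
        _add_disc(state.soc_count, d[0], d[1], factor_config.social_radius, 1.0)

    def remove(h: Household) -> None:
        _remove(state, h)
        drop_dwelling(h.dwelling)
        alive.discard(id(h))

    # (3) deaths by age
    for h in list(state.households):
        if h.age > h.death_age:
            remove(h)

    # (4) relocations, in shuffled order
    order = list(rng.permutation(len(state.households)))
    acting = [state.households[i] for i in order]
    for h in acting:
        if id(h) not in alive:
            continue
        if h.last_harvest >= h.nutrition_need:
            continue
        ctx = _build_context(
            state, landscape, factor_config,
            ref_farm=h.farm, ref_dwelling=h.dwelling,
            ref_age=h.age, ref_stock=h.total_corn, decider=h, cache=cache,
            need_family=need_family, need_arrays=need_arrays,
        )
        ctx.candidates = candidate_subset(connectivity, ctx)
        plot = select(ctx)
        if plot is None:
            remove(h)
            continue
        # Vacate old cells, claim the new farm, then site the dwelling.
        state.occupancy.farm[h.farm[1], h.farm[0]] = False
        state.occupancy.dwelling[h.dwelling[1], h.dwelling[0]] = False
        state.occupancy.farm[plot[1], plot[0]] = True
        dwelling = _find_dwelling(landscape, state.occupancy, water_ok, plot)
        if dwelling is None:
            state.occupancy.farm[plot[1], plot[0]] = False
            state.ledger.lost_to_removals += h.total_corn
            state.households.remove(h)
            drop_dwelling(h.dwelling)
            alive.discard(id(h))
            continue
        state.occupancy.dwelling[dwelling[1], dwelling[0]] = True
        drop_dwelling(h.dwelling)
        add_dwelling(dwelling)
        h.farm = plot
        h.dwelling = dwelling

    # (5) fission, in shuffled order
    order = list(rng.permutation(len(state.households)))
    parents = [state.households[i] for i in order]
    for h in parents:
        fertile = params.fertility_start_age <= h.age < h.fertility_end_age
        if not fertile or h.total_corn < h.nutrition_need:
            continue
        if rng.random() >= h.fertility:
            continue
        gift = params.maize_gift_to_child * h.total_corn
        ctx = _build_context(
            state, landscape, factor_config,
            ref_farm=h.farm, ref_dwelling=h.dwelling,
            ref_age=0.0, ref_stock=gift, decider=None, cache=cache,
            need_family=False, need_arrays=need_arrays,
        )
        if need_family:
            # The unborn child's family: parent, siblings, grandparent.
            fam = {h.id} | {o.id for o in state.households if o.parent_id == h.id}
            if h.parent_id is not None:
                fam.add(h.parent_id)
            ctx.family_ids = frozenset(fam)
        ctx.candidates = candidate_subset(connectivity, ctx)
        plot = select(ctx)
        if plot is None:
            continue  # fission fails; the parent keeps its corn
        state.occupancy.farm[plot[1], plot[0]] = True
        dwelling = _find_dwelling(landscape, state.occupancy, water_ok, plot)
        if dwelling is None:
            state.occupancy.farm[plot[1], plot[0]] = False
            continue
        state.occupancy.dwelling[dwelling[1], dwelling[0]] = True
        add_dwelling(dwelling)
        death_age, fertility, fertility_end = _draw_lifecycle(params, rng)
        frac = gift / h.total_corn
        child_corn = {v: amt * frac for v, amt in h.corn.items()}
        for v in h.corn:
            h.corn[v] *= 1.0 - frac
        state.households.append(
            Household(
                id=state.next_id,
                parent_id=h.id,
                age=0.0,
                farm=plot,
                dwelling=dwelling,
                corn=child_corn,
                nutrition_need=params.base_nutrition_need,
                death_age=death_age,
                fertility_end_age=fertility_end,
                fertility=fertility,
            )
        )
        state.next_id += 1

    for h in state.households:
        h.age += 1.0
    state.year = year + 1
    return state


def run_simulation(
    landscape: Landscape,
    params: SimulationParams,
    strategy,
    init: InitConfig | None = None,
    rng: np.random.Generator | int | None = None,
    factor_config: FactorConfig | None = None,
) -> SimulationResult:
    """Simulate the full span and score the trajectory against the target.

    ``rmse = sqrt(mean_t (simulated_t - target_t)^2)`` over every year of the
    span, the first year's count being the initial population.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    init = init or InitConfig()
    state = init_state(landscape, params, init, rng)
    counts = {landscape.start_year: state.count}
    for year in range(landscape.start_year, landscape.end_year):
        state = step_year(state, landscape, params, strategy, rng, factor_config)
        counts[year + 1] = state.count
    sim = [counts[y] for y in landscape.years]
    return SimulationResult(
        counts=counts, rmse=series_rmse(sim, landscape.target_series), params=params
    )


def series_rmse(simulated, target) -> float:
    """Root-mean-square error between two equal-length annual count series."""
    simulated = np.asarray(simulated, dtype=float)
    target = np.asarray(target, dtype=float)
    if simulated.shape != target.shape:
        raise ValueError(f"series lengths differ: {simulated.shape} vs {target.shape}")
    return float(np.sqrt(np.mean((simulated - target) ** 2)))
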