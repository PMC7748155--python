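"""Typed farm-plot-selection rule language.

A selection rule is ``argmax`` over a candidate set of an expression tree
built from nine factor terminals and the binary operators ``+`` and ``-``,
paired with exactly one social connectivity configuration that determines the
candidate set. Factors return desirability sub-scores min-max normalized to
[0, 1] within the candidate set, so heterogeneous statistics (distances,
yields, neighbour counts) are comparable.

Factors
-------
``F_Dist``   distance from the current (reference) farm; by default a higher
             sub-score means *farther* away, so the original nearest-plot
             behaviour is ``argmax(-F_Dist)``.
``F_Dry``    dryness of the plot's zone this year (drier = lower
             drought-adjusted baseline yield = higher sub-score).
``F_Qual``   soil quality.
``F_Yield``  most recent realized per-cell yield (0 if never farmed).
``F_Water``  number of active water sources within the social radius.
``F_Soc``    number of households dwelling within the social radius.
``F_HAge``   age homophily: nearby households of similar age score high.
``F_HAgri``  corn-stock homophily: nearby households of similar stock score high.
``F_Mig``    binary: 1 for plots in a different zone than the reference, else 0.

Connectivity configurations
---------------------------
``S_All``    every available plot (full information).
``S_Fam``    plots known to the household's family (self, parent, siblings,
             grandparents): available plots within the neighbour radius of a
             family member's dwelling.
``S_Neigh``  plots known to households (self included) dwelling within the
             neighbour radius of the decider.
``S_Perf``   plots known to the ``top_k`` households by total corn stock.

Composition is strongly typed: an expression node may receive a child only if
the child's return type equals the expected parameter type. With the shipped
grammar every factor returns the single ``score`` type and ``+``/``-`` map
``(score, score) -> score``, so any well-formed tree is well typed; the
machinery stays general so the factor set can be extended with other types.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FACTORS",
    "CONNECTIVITIES",
    "SCORE",
    "FactorSignature",
    "SIGNATURES",
    "Terminal",
    "BinOp",
    "RuleTree",
    "FactorConfig",
    "DecisionContext",
    "candidate_subset",
    "factor_subscores",
    "factor_subscore",
    "evaluate_rule",
    "extract_presence",
    "parse_rule",
    "format_rule",
    "RuleParseError",
]

FACTORS = ("Dist", "Dry", "Qual", "Yield", "Water", "Soc", "HAge", "HAgri", "Mig")
CONNECTIVITIES = ("S_All", "S_Fam", "S_Neigh", "S_Perf")

#: The single value type of the shipped grammar.
SCORE = "score"


@dataclass(frozen=True)
class FactorSignature:
    """Typed signature of a factor or operator.

    ``arity == 0`` marks a terminal. A node with signature ``f`` may take a
    child with signature ``g`` in slot ``k`` iff
    ``g.return_type == f.param_types[k]``.
    """

    name: str
    return_type: str
    param_types: tuple[str, ...] = ()

    @property
    def arity(self) -> int:
        return len(self.param_types)


SIGNATURES: dict[str, FactorSignature] = {
    **{name: FactorSignature(name, SCORE) for name in FACTORS},
    "+": FactorSignature("+", SCORE, (SCORE, SCORE)),
    "-": FactorSignature("-", SCORE, (SCORE, SCORE)),
}


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Terminal:
    """Factor terminal node."""

    name: str

    def __post_init__(self):
        if self.name not in FACTORS:
            raise ValueError(f"unknown factor terminal: {self.name!r}")


@dataclass(frozen=True)
class BinOp:
    """Binary ``+`` or ``-`` node."""

    op: str
    left: "Node"
    right: "Node"

    def __post_init__(self):
        if self.op not in ("+", "-"):
            raise ValueError(f"unknown operator: {self.op!r}")


Node = Terminal | BinOp


def node_depth(node: Node) -> int:
    """Tree depth in edges (a lone terminal has depth 0)."""
    if isinstance(node, Terminal):
        return 0
    return 1 + max(node_depth(node.left), node_depth(node.right))


def node_count(node: Node) -> int:
    if isinstance(node, Terminal):
        return 1
    return 1 + node_count(node.left) + node_count(node.right)


def iter_nodes(node: Node):
    """Yield nodes in pre-order."""
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        if isinstance(n, BinOp):
            stack.append(n.right)
            stack.append(n.left)


def check_types(node: Node) -> str:
    """Return the tree's value type; raise TypeError on a typing violation."""
    if isinstance(node, Terminal):
        return SIGNATURES[node.name].return_type
    sig = SIGNATURES[node.op]
    for k, child in enumerate((node.left, node.right)):
        got = check_types(child)
        if got != sig.param_types[k]:
            raise TypeError(
                f"operator {node.op!r} slot {k} expects {sig.param_types[k]}, got {got}"
            )
    return sig.return_type


@dataclass(frozen=True)
class RuleTree:
    """A farm-selection rule: one connectivity plus an expression tree."""

    connectivity: str
    root: Node

    def __post_init__(self):
        if self.connectivity not in CONNECTIVITIES:
            raise ValueError(f"unknown connectivity: {self.connectivity!r}")
        check_types(self.root)

    @property
    def depth(self) -> int:
        return node_depth(self.root)

    def presence(self) -> dict[str, int]:
        # Cached: rules are immutable and presence is read on every decision.
        cached = getattr(self, "_presence_cache", None)
        if cached is None:
            cached = extract_presence(self)
            object.__setattr__(self, "_presence_cache", cached)
        return cached

    def __str__(self) -> str:
        return format_rule(self)


def extract_presence(rule: RuleTree | Node) -> dict[str, int]:
    """Signed integer coefficient of each factor in the rule's linear expansion.

    ``coeffs(F) = e_F``; ``coeffs(a + b) = coeffs(a) + coeffs(b)``;
    ``coeffs(a - b) = coeffs(a) - coeffs(b)``. All nine factors are reported,
    zeros included.
    """
    node = rule.root if isinstance(rule, RuleTree) else rule
    coeffs = dict.fromkeys(FACTORS, 0)

    def walk(n: Node, sign: int) -> None:
        if isinstance(n, Terminal):
            coeffs[n.name] += sign
        else:
            walk(n.left, sign)
            walk(n.right, sign if n.op == "+" else -sign)

    walk(node, 1)
    return coeffs


# ---------------------------------------------------------------------------
# Canonical text grammar
# ---------------------------------------------------------------------------

class RuleParseError(ValueError):
    """Raised for rule strings outside the canonical grammar."""


_RULE_RE = re.compile(r"^\s*argmax\[(?P<conn>\w+)\]\((?P<expr>.*)\)\s*$")
_TERM_RE = re.compile(r"^(?:(?P<coeff>\d+)\s*\*\s*)?F_(?P<name>\w+)$")


def parse_rule(text: str) -> RuleTree:
    """Parse a canonical rule string, e.g. ``argmax[S_All](F_Qual + 2*F_Mig)``.

    The grammar is the linear form: signed integer multiples of factor
    terminals joined by ``+``/``-``. A coefficient ``k`` expands to ``k``
    repeated terminals, so ``format(parse(t))`` is the canonicalization of
    ``t`` (terms merged and ordered by the canonical factor order).
    """
    m = _RULE_RE.match(text)
    if not m:
        raise RuleParseError(f"not a rule string: {text!r}")
    conn = m.group("conn")
    if conn not in CONNECTIVITIES:
        raise RuleParseError(f"unknown connectivity token: {conn!r}")

    expr = m.group("expr").strip()
    if expr in ("", "0"):
        # Canonical zero rule: scores every candidate 0.0.
        zero = BinOp("-", Terminal(FACTORS[0]), Terminal(FACTORS[0]))
        return RuleTree(conn, zero)

    # Tokenize into signed terms.
    parts = re.split(r"(?=[+-])", expr.replace(" ", ""))
    coeffs = dict.fromkeys(FACTORS, 0)
    for part in parts:
        if not part:
            continue
        sign = 1
        if part[0] in "+-":
            sign = 1 if part[0] == "+" else -1
            part = part[1:]
        tm = _TERM_RE.match(part)
        if not tm:
            raise RuleParseError(f"bad term {part!r} in rule {text!r}")
        name = tm.group("name")
        if name not in FACTORS:
            raise RuleParseError(f"unknown factor token: F_{name}")
        k = int(tm.group("coeff")) if tm.group("coeff") else 1
        coeffs[name] += sign * k

    return RuleTree(conn, _linear_tree(coeffs))


def _linear_tree(coeffs: dict[str, int]) -> Node:
    """Build a left-deep Add/Sub chain realizing the given coefficients."""
    tree: Node | None = None
    for name in FACTORS:
        k = coeffs.get(name, 0)
        for _ in range(abs(k)):
            term = Terminal(name)
            if tree is None:
                if k > 0:
                    tree = term
                else:
                    # Unary minus is spelled (F - F) - F.
                    tree = BinOp("-", BinOp("-", term, Terminal(name)), term)
            else:
                tree = BinOp("+" if k > 0 else "-", tree, term)
    if tree is None:
        tree = BinOp("-", Terminal(FACTORS[0]), Terminal(FACTORS[0]))
    return tree


def format_rule(rule: RuleTree) -> str:
    """Canonical string form: linear expansion in canonical factor order."""
    coeffs = extract_presence(rule)
    parts: list[str] = []
    for name in FACTORS:
        k = coeffs[name]
        if k == 0:
            continue
        mag = f"{abs(k)}*F_{name}" if abs(k) != 1 else f"F_{name}"
        if not parts:
            parts.append(mag if k > 0 else f"-{mag}")
        else:
            parts.append(f" + {mag}" if k > 0 else f" - {mag}")
    body = "".join(parts) if parts else "0"
    return f"argmax[{rule.connectivity}]({body})"


# ---------------------------------------------------------------------------
# Decision contexts and candidate subsets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorConfig:
    """Radii and sizes left open by the factor definitions.

    social_radius
        Radius (cells) for social presence, homophily and water counting.
    neighbor_radius
        Radius (cells) defining which plots a household "knows" (around its
        dwelling) and which households count as neighbours for ``S_Neigh``.
    top_k
        Number of best-performing households whose knowledge ``S_Perf`` pools.
    dist_farther_is_better
        Orientation of ``F_Dist``; the default makes ``argmax(-F_Dist)`` the
        classic nearest-available-plot rule.
    """

    social_radius: float = 5.0
    neighbor_radius: float = 10.0
    top_k: int = 10
    dist_farther_is_better: bool = True


@dataclass
class StepCache:
    """Optional per-step precomputed grids for fast factor evaluation.

    ``soc_count`` counts household dwellings within the social radius of each
    cell; ``water_count`` counts active water sources likewise; ``dry`` holds
    this year's zone dryness per cell. When present these replace the
    per-decision pairwise computations with grid lookups; results are
    identical.
    """

    soc_count: np.ndarray | None = None  # (h, w) float
    water_count: np.ndarray | None = None  # (h, w) float
    dry: np.ndarray | None = None  # (h, w) float


@dataclass
class DecisionContext:
    """Everything a rule needs to score candidate plots for one decision.

    Household state is carried as parallel arrays (dwelling coordinates, ages,
    corn stocks, ids) so factor sub-scores vectorize over candidates. The
    ``ref_*`` fields describe the deciding household (for a newly fissioned
    child these are inherited from the parent: the child decides from the
    parent's farm location with age 0 and the maize gift as its stock).
    """

    landscape: "object"
    year: int
    ref_farm: tuple[int, int]
    ref_dwelling: tuple[int, int]
    ref_zone: int
    ref_age: float
    ref_stock: float
    decider_id: int | None
    hh_ids: np.ndarray
    hh_dwellings: np.ndarray  # (m, 2) of (x, y)
    hh_ages: np.ndarray
    hh_stocks: np.ndarray
    family_ids: frozenset[int] = frozenset()
    available: np.ndarray | None = None  # (height, width) bool
    last_yield: np.ndarray | None = None  # (height, width) realized kg
    candidates: np.ndarray | None = None  # (n, 2) of (x, y)
    config: FactorConfig = field(default_factory=FactorConfig)
    cache: StepCache | None = None
    _subscores: dict = field(default_factory=dict, repr=False)

    def with_candidates(self, candidates: np.ndarray) -> "DecisionContext":
        return replace(self, candidates=candidates, _subscores={})


def _available_coords(ctx: DecisionContext) -> np.ndarray:
    ys, xs = np.nonzero(ctx.available)
    return np.column_stack([xs, ys])


def _known_plots(ctx: DecisionContext, dwellings: np.ndarray) -> np.ndarray:
    """Available plots within the neighbour radius of any given dwelling."""
    coords = _available_coords(ctx)
    if len(coords) == 0 or len(dwellings) == 0:
        return coords[:0]
    known = (_pairwise_d2(coords, dwellings) <= ctx.config.neighbor_radius**2).any(axis=1)
    return coords[known]


def candidate_subset(connectivity: str, ctx: DecisionContext) -> np.ndarray:
    """Candidate plots ``s`` for a decision, as an ``(n, 2)`` array of (x, y).

    May be empty; the caller treats an empty set as relocation failure.
    """
    if connectivity == "S_All":
        return _available_coords(ctx)

    own = np.array([ctx.ref_dwelling], dtype=np.int64)
    if connectivity == "S_Fam":
        mask = np.isin(ctx.hh_ids, list(ctx.family_ids))
        dwellings = np.vstack([own, ctx.hh_dwellings[mask]])
        return _known_plots(ctx, dwellings)
    if connectivity == "S_Neigh":
        if len(ctx.hh_dwellings):
            d2 = ((ctx.hh_dwellings - np.asarray(ctx.ref_dwelling)) ** 2).sum(axis=1)
            near = ctx.hh_dwellings[d2 <= ctx.config.neighbor_radius**2]
            dwellings = np.vstack([own, near])
        else:
            dwellings = own
        return _known_plots(ctx, dwellings)
    if connectivity == "S_Perf":
        if len(ctx.hh_stocks):
            # Top-k by stock, ties broken by household id for determinism.
            order = np.lexsort((ctx.hh_ids, -ctx.hh_stocks))
            dwellings = ctx.hh_dwellings[order[: ctx.config.top_k]]
            dwellings = np.vstack([own, dwellings])
        else:
            dwellings = own
        return _known_plots(ctx, dwellings)
    raise ValueError(f"unknown connectivity: {connectivity!r}")


# ---------------------------------------------------------------------------
# Factor sub-scores
# ---------------------------------------------------------------------------

def _minmax(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        # All candidates tie: neutral 0.5 rather than NaN.
        return np.full(raw.shape, 0.5)
    return (raw - lo) / (hi - lo)


def _others_mask(ctx: DecisionContext) -> np.ndarray:
    if ctx.decider_id is None:
        return np.ones(len(ctx.hh_ids), dtype=bool)
    return ctx.hh_ids != ctx.decider_id


def _pairwise_d2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(n, m) squared Euclidean distances between integer coordinate sets.

    For larger products uses the |p-q|^2 = |p|^2 + |q|^2 - 2 p.q expansion;
    every intermediate is an integer-valued float well below 2^53, so the
    result is exact either way.
    """
    if len(a) * len(b) < 4000:
        return (
            (a[:, None, 0] - b[None, :, 0]) ** 2.0
            + (a[:, None, 1] - b[None, :, 1]) ** 2.0
        )
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    return (
        (a * a).sum(axis=1)[:, None]
        + (b * b).sum(axis=1)[None, :]
        - 2.0 * (a @ b.T)
    )


def _within_radius(plots: np.ndarray, points: np.ndarray, radius: float) -> np.ndarray:
    """(n_plots, n_points) bool: point within ``radius`` of plot."""
    if len(points) == 0:
        return np.zeros((len(plots), 0), dtype=bool)
    return _pairwise_d2(plots, points) <= radius**2


def _near_others(ctx: DecisionContext, plots: np.ndarray) -> np.ndarray:
    """Within-social-radius mask against non-decider households, shared by
    the social-presence and homophily factors of one decision."""
    cached = ctx._subscores.get("__near_others__")
    if cached is None:
        others = ctx.hh_dwellings[_others_mask(ctx)]
        cached = _within_radius(plots, others, ctx.config.social_radius)
        ctx._subscores["__near_others__"] = cached
    return cached


def _grid_take(grid: np.ndarray, ctx: DecisionContext) -> np.ndarray:
    """Fetch a (height, width) grid at the candidate plots (flat take)."""
    flat = ctx._subscores.get("__flat__")
    if flat is None:
        plots = ctx.candidates
        flat = plots[:, 1] * grid.shape[1] + plots[:, 0]
        ctx._subscores["__flat__"] = flat
    return grid.ravel()[flat]


def _raw_statistic(factor: str, plots: np.ndarray, ctx: DecisionContext) -> np.ndarray:
    ls = ctx.landscape
    xs, ys = plots[:, 0], plots[:, 1]
    cfg = ctx.config

    cache = ctx.cache

    if factor == "Dist":
        d = np.hypot(xs - ctx.ref_farm[0], ys - ctx.ref_farm[1])
        return d if cfg.dist_farther_is_better else -d
    if factor == "Qual":
        return _grid_take(ls.quality, ctx)
    if factor == "Dry":
        # Drier zones have lower drought-adjusted baseline yield this year.
        if cache is not None and cache.dry is not None:
            return _grid_take(cache.dry, ctx)
        return -ls.baseline_yield(ls.zone[ys, xs], ctx.year)
    if factor == "Yield":
        if ctx.last_yield is None:
            return np.zeros(len(plots))
        return _grid_take(ctx.last_yield, ctx)
    if factor == "Water":
        if cache is not None and cache.water_count is not None:
            return _grid_take(cache.water_count, ctx)
        src = np.array(
            [(w.x, w.y) for w in ls.active_water_sources(ctx.year)], dtype=np.int64
        ).reshape(-1, 2)
        return _within_radius(plots, src, cfg.social_radius).sum(axis=1).astype(float)
    if factor == "Soc":
        if cache is not None and cache.soc_count is not None:
            counts = _grid_take(cache.soc_count, ctx)
            if ctx.decider_id is not None:
                # The density grid includes the decider's own dwelling.
                dx, dy = ctx.ref_dwelling
                own = (xs - dx) ** 2 + (ys - dy) ** 2 <= cfg.social_radius**2
                counts = counts - own
            return counts
        return _near_others(ctx, plots).sum(axis=1).astype(float)
    if factor in ("HAge", "HAgri"):
        om = _others_mask(ctx)
        attr = (ctx.hh_ages if factor == "HAge" else ctx.hh_stocks)[om]
        ref = ctx.ref_age if factor == "HAge" else ctx.ref_stock
        near = _near_others(ctx, plots)
        counts = near.sum(axis=1)
        diffs = np.abs(attr - ref)
        total = near @ diffs
        raw = np.full(len(plots), np.nan)
        nz = counts > 0
        raw[nz] = -total[nz] / counts[nz]
        if nz.any():
            raw[~nz] = raw[nz].min()  # isolated plots score as bad as the worst
        else:
            raw[:] = 0.0
        return raw
    raise ValueError(f"unknown factor: {factor!r}")


def factor_subscores(factor: str, ctx: DecisionContext) -> np.ndarray:
    """Sub-scores in [0, 1] of every candidate plot for one factor.

    Min-max normalized over the candidate set; ``F_Mig`` is binary and exempt
    from normalization. Results are cached on the context.
    """
    if factor in ctx._subscores:
        return ctx._subscores[factor]
    plots = ctx.candidates
    if plots is None or len(plots) == 0:
        return np.zeros(0)
    if factor == "Mig":
        score = (_grid_take(ctx.landscape.zone, ctx) != ctx.ref_zone).astype(float)
    else:
        score = _minmax(_raw_statistic(factor, plots, ctx))
    ctx._subscores[factor] = score
    return score


def _bulk_subscores(names: list[str], ctx: DecisionContext) -> None:
    """Compute several factors' sub-scores with shared normalization passes.

    Per-element arithmetic is identical to :func:`factor_subscores`; only the
    min/max reductions are batched across factors.
    """
    plots = ctx.candidates
    n = len(plots)
    rows = np.empty((len(names), n))
    for j, f in enumerate(names):
        if f == "Mig":
            rows[j] = _grid_take(ctx.landscape.zone, ctx) != ctx.ref_zone
        else:
            rows[j] = _raw_statistic(f, plots, ctx)
    lo = rows.min(axis=1)
    hi = rows.max(axis=1)
    span = hi - lo
    norm = (rows - lo[:, None]) / np.where(span == 0.0, 1.0, span)[:, None]
    for j, f in enumerate(names):
        if f == "Mig":
            ctx._subscores[f] = rows[j]
        elif span[j] == 0.0:
            ctx._subscores[f] = np.full(n, 0.5)
        else:
            ctx._subscores[f] = norm[j]


def factor_subscore(factor: str, plot: tuple[int, int], ctx: DecisionContext) -> float:
    """Sub-score of a single candidate plot (scalar convenience wrapper)."""
    plots = ctx.candidates
    idx = np.nonzero((plots[:, 0] == plot[0]) & (plots[:, 1] == plot[1]))[0]
    if idx.size == 0:
        raise ValueError(f"plot {plot} is not a candidate")
    return float(factor_subscores(factor, ctx)[idx[0]])


# ---------------------------------------------------------------------------
# Rule evaluation
# ---------------------------------------------------------------------------

def _scores(rule: RuleTree, ctx: DecisionContext) -> np.ndarray:
    """Candidate scores via the rule's linear expansion.

    ``+``/``-`` trees expand exactly to integer-weighted sums of factor
    sub-scores; accumulating in the canonical factor order makes the result
    independent of tree shape.
    """
    coeffs = rule.presence()
    used = [f for f in FACTORS if coeffs[f]]
    missing = [f for f in used if f not in ctx._subscores]
    if len(missing) > 1 and len(ctx.candidates):
        _bulk_subscores(missing, ctx)
    scores = np.zeros(len(ctx.candidates))
    for name in used:
        scores = scores + coeffs[name] * factor_subscores(name, ctx)
    return scores


def evaluate_tree(node: Node, ctx: DecisionContext) -> np.ndarray:
    """Direct recursive tree evaluation over the candidate vector."""
    if isinstance(node, Terminal):
        return factor_subscores(node.name, ctx)
    left = evaluate_tree(node.left, ctx)
    right = evaluate_tree(node.right, ctx)
    return left + right if node.op == "+" else left - right


def evaluate_rule(rule: RuleTree, ctx: DecisionContext) -> tuple[int, int] | None:
    """Argmax of the rule expression over the candidate set.

    Ties break deterministically on lowest (y, x). Returns ``None`` iff the
    candidate set is empty.
    """
    plots = ctx.candidates
    if plots is None or len(plots) == 0:
        return None
    scores = _scores(rule, ctx)
    best = scores.max()
    tied = np.nonzero(scores == best)[0]
    if len(tied) > 1:
        order = np.lexsort((plots[tied, 0], plots[tied, 1]))
        i = tied[order[0]]
    else:
        i = tied[0]
    return int(plots[i, 0]), int(plots[i, 1])
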