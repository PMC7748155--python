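"""Random-forest factor-importance pipeline.

Regresses simulation fitness (RMSE, lower is better) on the nine signed
factor-presence coefficients of every rule the genetic program evaluated,
then ranks factors three ways:

* **gini importance** — total impurity (variance) decrease attributed to each
  feature across the forest's splits, normalized to sum 1;
* **permutation importance** — mean increase in held-out squared error when a
  feature column is shuffled, over independent repeats;
* **joint contribution** — a decision-path decomposition of every forest
  prediction. Walking each tree root-to-leaf, the change in node mean at each
  split is attributed to the *set* of distinct features encountered on the
  path so far, so interacting features accumulate shared mass. For every
  sample, ``bias + sum(subset contributions) == forest prediction`` exactly.

Also provides the one-tailed Mann-Whitney U comparison matrices used to
order connectivity configurations, factor importances and presence values,
the presence-value fitness summaries, and the designed-strategy robustness
comparison against the original nearest-plot behaviour.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation
from sklearn.model_selection import train_test_split

from .abm import DEFAULT_PARAM_RANGES, InitConfig, draw_params, run_simulation
from .landscape import Landscape
from .rules import FACTORS, FactorConfig, parse_rule

__all__ = [
    "DEFAULT_TREE_GRID",
    "ForestModel",
    "fit_forest",
    "gini_importance",
    "permutation_importance",
    "decompose_forest",
    "JointContributionReport",
    "joint_contributions",
    "mann_whitney",
    "ComparisonMatrix",
    "mann_whitney_matrix",
    "presence_fitness_summary",
    "StrategyComparison",
    "compare_strategies",
    "synthetic_presence_table",
]

#: Forest sizes searched by default: 10..100 by 10, then 150..1000 by 50.
DEFAULT_TREE_GRID: tuple[int, ...] = tuple(range(10, 101, 10)) + tuple(range(150, 1001, 50))


@dataclass
class ForestModel:
    """A fitted regression forest plus its train/test split record."""

    model: RandomForestRegressor
    n_trees: int
    test_r2: float
    X_train: np.ndarray
    X_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray
    features: tuple[str, ...] = FACTORS


def _presence_matrix(table: pd.DataFrame) -> np.ndarray:
    return table[list(FACTORS)].to_numpy(dtype=float)


def fit_forest(
    table: pd.DataFrame,
    grid: tuple[int, ...] = DEFAULT_TREE_GRID,
    split: float = 0.1,
    rng: np.random.Generator | int | None = None,
    connectivity: str | None = "S_All",
    max_depth: int | None = None,
) -> ForestModel:
    """Search the tree-count grid and keep the forest with best held-out R².

    The table is restricted to ``connectivity`` rows (default ``S_All``, the
    configuration the downstream analyses focus on; pass ``None`` to keep
    all rows). One 90/10 train/test split is drawn and reused across the
    whole grid so tree counts are compared on identical data.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if connectivity is not None:
        table = table[table["connectivity"] == connectivity]
    if len(table) < 50:
        raise ValueError(
            f"only {len(table)} rows after filtering; need at least 50 to fit a forest"
        )
    X = _presence_matrix(table)
    y = table["fitness"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("fitness column contains NaN")

    split_seed = int(rng.integers(2**31))
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=split, random_state=split_seed)

    best: ForestModel | None = None
    for n in grid:
        forest_seed = int(rng.integers(2**31))
        model = RandomForestRegressor(
            n_estimators=int(n), random_state=forest_seed, n_jobs=1, max_depth=max_depth
        )
        model.fit(X_tr, y_tr)
        if np.var(y_te) == 0.0:
            # Constant held-out target: R^2 is undefined; score by test error.
            r2 = 1.0 - float(np.mean((model.predict(X_te) - y_te) ** 2))
        else:
            r2 = float(model.score(X_te, y_te))
        if best is None or r2 > best.test_r2:
            best = ForestModel(model, int(n), r2, X_tr, X_te, y_tr, y_te)
    return best


def gini_importance(fm: ForestModel) -> pd.Series:
    """Per-factor impurity-decrease shares (non-negative, summing to 1)."""
    return pd.Series(fm.model.feature_importances_, index=list(fm.features))


def permutation_importance(
    fm: ForestModel,
    table: pd.DataFrame | None = None,
    repeats: int = 10,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Mean (+/- sd) increase in squared error under per-factor shuffling.

    Scored on the held-out split unless ``table`` supplies other data.
    Returns a frame with ``mean``, ``sd`` and per-repeat columns.
    """
    if repeats < 2:
        raise ValueError("permutation importance needs at least 2 repeats")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if table is not None:
        X, y = _presence_matrix(table), table["fitness"].to_numpy(dtype=float)
    else:
        X, y = fm.X_test, fm.y_test
    res = _sk_permutation(
        fm.model, X, y,
        n_repeats=repeats,
        random_state=int(rng.integers(2**31)),
        scoring="neg_mean_squared_error",
        n_jobs=1,
    )
    out = pd.DataFrame(res.importances, index=list(fm.features))
    out.insert(0, "sd", res.importances_std)
    out.insert(0, "mean", res.importances_mean)
    return out


# ---------------------------------------------------------------------------
# Joint contribution (decision-path decomposition)
# ---------------------------------------------------------------------------

def decompose_forest(fm: ForestModel, X: np.ndarray) -> tuple[float, dict[frozenset, np.ndarray]]:
    """Decompose forest predictions along decision paths.

    Returns ``(bias, contributions)`` where ``bias`` is the mean of the root
    node values across trees and ``contributions`` maps each encountered
    feature subset (as a frozenset of feature names) to the per-sample signed
    contribution, averaged over trees. Invariant: for every sample,
    ``bias + sum_S contributions[S] == forest prediction``.
    """
    X = np.asarray(X, dtype=np.float32)
    n = len(X)
    features = fm.features
    acc: dict[int, np.ndarray] = {}  # feature bitmask -> per-sample sums over trees
    bias = 0.0
    for est in fm.model.estimators_:
        t = est.tree_
        value = t.value.reshape(-1)
        bias += value[0]
        # Iterative DFS partitioning the sample index set.
        stack = [(0, np.arange(n), 0)]
        while stack:
            node, idx, mask = stack.pop()
            if t.children_left[node] == -1 or len(idx) == 0:
                continue
            f = int(t.feature[node])
            go_left = X[idx, f] <= t.threshold[node]
            child_mask = mask | (1 << f)
            for child, cidx in (
                (int(t.children_left[node]), idx[go_left]),
                (int(t.children_right[node]), idx[~go_left]),
            ):
                if len(cidx) == 0:
                    continue
                delta = value[child] - value[node]
                if delta != 0.0:
                    arr = acc.get(child_mask)
                    if arr is None:
                        arr = acc[child_mask] = np.zeros(n)
                    arr[cidx] += delta
                stack.append((child, cidx, child_mask))
    n_trees = len(fm.model.estimators_)
    bias /= n_trees
    contributions = {
        frozenset(features[i] for i in range(len(features)) if m >> i & 1): a / n_trees
        for m, a in acc.items()
    }
    return float(bias), contributions


@dataclass
class JointContributionReport:
    """Normalized contribution scores of factor subsets of size <= 3."""

    scores: pd.Series  # index: tuple of factor names, sorted by score desc
    bias: float
    max_subset_size: int = 3

    def top(self, k: int = 10) -> pd.Series:
        return self.scores.head(k)


def joint_contributions(
    fm: ForestModel,
    table: pd.DataFrame | None = None,
    max_subset_size: int = 3,
) -> JointContributionReport:
    """Aggregate decision-path contributions into subset importance scores.

    Per sample and subset the signed path contributions are averaged over
    trees; the report scores each subset by the mean absolute contribution
    over samples, keeps subsets up to ``max_subset_size`` factors, and
    normalizes the kept scores to sum 1.
    """
    X = _presence_matrix(table) if table is not None else fm.X_test
    bias, contrib = decompose_forest(fm, X)
    raw = {
        tuple(sorted(s, key=FACTORS.index)): float(np.mean(np.abs(a)))
        for s, a in contrib.items()
        if 0 < len(s) <= max_subset_size
    }
    total = sum(raw.values())
    if total > 0:
        raw = {k: v / total for k, v in raw.items()}
    # explicit object index: subset keys are tuples, not MultiIndex levels
    scores = pd.Series(
        list(raw.values()),
        index=pd.Index(list(raw.keys()), dtype=object, tupleize_cols=False),
        dtype=float,
    ).sort_values(ascending=False)
    return JointContributionReport(scores=scores, bias=bias, max_subset_size=max_subset_size)


# ---------------------------------------------------------------------------
# Mann-Whitney comparisons
# ---------------------------------------------------------------------------

def mann_whitney(a, b, alternative: str = "less") -> tuple[float, float]:
    """One-tailed Mann-Whitney U test of ``a`` versus ``b``.

    Uses the exact null distribution when the smaller sample has at most 8
    observations and the pooled data are tie-free, otherwise the normal
    approximation with tie correction. Completely tied data short-circuit to
    ``p = 1`` instead of producing NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonMatrix:
    """Pairwise one-tailed Mann-Whitney results over labelled groups."""

    U: pd.DataFrame
    p: pd.DataFrame
    reject: pd.DataFrame
    alternative: str
    alpha: float


def mann_whitney_matrix(
    groups: dict[str, np.ndarray],
    alternative: str = "less",
    alpha: float = 0.05,
) -> ComparisonMatrix:
    """Test every ordered pair (A, B): H1 ``values(A) alternative values(B)``.

    The diagonal is undefined (NaN). No multiplicity correction is applied;
    each cell is tested at ``alpha``.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    U = pd.DataFrame(np.nan, index=labels, columns=labels)
    P = pd.DataFrame(np.nan, index=labels, columns=labels)
    R = pd.DataFrame(False, index=labels, columns=labels)
    for la, lb in itertools.permutations(labels, 2):
        u, p = mann_whitney(groups[la], groups[lb], alternative=alternative)
        U.loc[la, lb] = u
        P.loc[la, lb] = p
        R.loc[la, lb] = p < alpha
    return ComparisonMatrix(U=U, p=P, reject=R, alternative=alternative, alpha=alpha)


def presence_fitness_summary(
    table: pd.DataFrame,
    min_count: int = 200,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, ComparisonMatrix]]:
    """Fitness distribution per factor presence value.

    Only presence values recorded in at least ``min_count`` rules enter the
    summary and the per-factor pairwise comparison matrices (H1: fitness at
    presence A is stochastically less than at presence B).
    """
    records = []
    matrices: dict[str, ComparisonMatrix] = {}
    for factor in FACTORS:
        grouped = table.groupby(factor)["fitness"]
        kept = {int(v): g.to_numpy() for v, g in grouped if len(g) >= min_count}
        for v in sorted(kept):
            g = kept[v]
            records.append(
                {
                    "factor": factor,
                    "presence": v,
                    "count": len(g),
                    "median": float(np.median(g)),
                    "q1": float(np.quantile(g, 0.25)),
                    "q3": float(np.quantile(g, 0.75)),
                }
            )
        if len(kept) >= 2:
            matrices[factor] = mann_whitney_matrix(
                {str(v): kept[v] for v in sorted(kept)}, alternative="less", alpha=alpha
            )
    summary = pd.DataFrame(
        records, columns=["factor", "presence", "count", "median", "q1", "q3"]
    )
    return summary, matrices


# ---------------------------------------------------------------------------
# Designed-strategy robustness comparison
# ---------------------------------------------------------------------------

@dataclass
class StrategyComparison:
    """RMSE distributions of candidate strategies and tests vs the baseline."""

    distributions: pd.DataFrame  # columns: strategy, run, rmse
    tests: pd.DataFrame | None  # one row per non-baseline strategy
    baseline: str
    message: str = ""


def compare_strategies(
    strategies: list[str],
    landscape: Landscape,
    n_runs: int = 100,
    param_ranges: dict | None = None,
    baseline: str = "argmax[S_All](-F_Dist)",
    rng: np.random.Generator | int | None = None,
    init: InitConfig | None = None,
    factor_config: FactorConfig | None = None,
    alpha: float = 0.05,
) -> StrategyComparison:
    """Robustness comparison under randomized parameter initialization.

    Each strategy (plus the baseline) is simulated ``n_runs`` times with the
    demographic parameters redrawn from their windows every run; each
    designed strategy is then tested one-tailed (H1: its RMSE is
    stochastically lower than the baseline's). With ``n_runs == 1`` the
    distributions are returned but the tests are refused.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    param_ranges = param_ranges if param_ranges is not None else dict(DEFAULT_PARAM_RANGES)
    init = init or InitConfig()
    all_strategies = list(strategies)
    if baseline not in all_strategies:
        all_strategies.append(baseline)

    master = int(rng.integers(2**31))
    rows = []
    for s_idx, text in enumerate(all_strategies):
        rule = parse_rule(text)
        for run in range(n_runs):
            run_rng = np.random.default_rng([master, s_idx, run])
            params = draw_params(param_ranges, run_rng)
            result = run_simulation(
                landscape, params, rule, init=init, rng=run_rng, factor_config=factor_config
            )
            rows.append({"strategy": text, "run": run, "rmse": result.rmse})
    dist = pd.DataFrame(rows)

    if n_runs < 2:
        return StrategyComparison(
            distributions=dist, tests=None, baseline=baseline,
            message="tests refused: need at least 2 runs per strategy",
        )
    base = dist.loc[dist["strategy"] == baseline, "rmse"].to_numpy()
    tests = []
    for text in strategies:
        if text == baseline:
            continue
        vals = dist.loc[dist["strategy"] == text, "rmse"].to_numpy()
        u, p = mann_whitney(vals, base, alternative="less")
        tests.append(
            {
                "strategy": text,
                "baseline": baseline,
                "median_rmse": float(np.median(vals)),
                "baseline_median_rmse": float(np.median(base)),
                "U": u,
                "p": p,
                "significant": p < alpha,
            }
        )
    return StrategyComparison(distributions=dist, tests=pd.DataFrame(tests), baseline=baseline)


# ---------------------------------------------------------------------------
# Synthetic presence->fitness tables (importance-recovery studies)
# ---------------------------------------------------------------------------

def synthetic_presence_table(
    n: int = 5000,
    effects: dict[str, float] | None = None,
    interaction: tuple[str, str, float] | None = None,
    noise_sd: float = 5.0,
    presence_low: int = -3,
    presence_high: int = 5,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Presence table with planted linear effects and an optional interaction.

    Presence coefficients are drawn iid uniform on the integer range
    ``[presence_low, presence_high]`` (the bulk of the range the genetic
    program explores). The default planted signal is
    ``30*Qual - 10*Soc + 5*Mig + N(0, noise_sd)``; an ``interaction``
    ``(A, B, w)`` adds ``w * 1[A > 0 and B > 0]``. Connectivity is S_All.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    effects = effects if effects is not None else {"Qual": 30.0, "Soc": -10.0, "Mig": 5.0}
    X = rng.integers(presence_low, presence_high + 1, size=(n, len(FACTORS)))
    y = rng.normal(0.0, noise_sd, size=n)
    for name, w in effects.items():
        y = y + w * X[:, FACTORS.index(name)]
    if interaction is not None:
        a, b, w = interaction
        y = y + w * ((X[:, FACTORS.index(a)] > 0) & (X[:, FACTORS.index(b)] > 0))
    table = pd.DataFrame(X, columns=list(FACTORS))
    table["connectivity"] = "S_All"
    table["fitness"] = y
    table["run"] = 0
    table["generation"] = 0
    return table
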