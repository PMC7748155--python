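"""Random-forest importance pipeline: fitting, three importance measures,
Mann-Whitney machinery, presence summaries, strategy comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from emdisc.importance import (
    ForestModel,
    compare_strategies,
    decompose_forest,
    fit_forest,
    gini_importance,
    joint_contributions,
    mann_whitney,
    mann_whitney_matrix,
    permutation_importance,
    presence_fitness_summary,
    synthetic_presence_table,
)
from emdisc.rules import FACTORS


@pytest.fixture(scope="module")
def planted_forest():
    table = synthetic_presence_table(n=2000, seed=0)
    return table, fit_forest(table, grid=(60,), rng=0)


# ---------------------------------------------------------------------------
# forest fitting
# ---------------------------------------------------------------------------

def test_constant_fitness_is_fit_perfectly():
    table = synthetic_presence_table(n=200, effects={}, noise_sd=0.0, seed=1)
    table["fitness"] = 42.0
    fm = fit_forest(table, grid=(10,), rng=0)
    np.testing.assert_allclose(fm.model.predict(fm.X_test), 42.0)


def test_too_few_rows_are_refused():
    table = synthetic_presence_table(n=30, seed=0)
    with pytest.raises(ValueError, match="50"):
        fit_forest(table, grid=(10,), rng=0)


def test_tree_count_selection_is_deterministic():
    table = synthetic_presence_table(n=400, seed=2)
    a = fit_forest(table, grid=(10, 30), rng=7)
    b = fit_forest(table, grid=(10, 30), rng=7)
    assert a.n_trees == b.n_trees and a.test_r2 == b.test_r2


def test_planted_effects_give_high_test_r2(planted_forest):
    _, fm = planted_forest
    assert fm.test_r2 > 0.8


def test_non_default_connectivity_rows_are_filtered():
    table = synthetic_presence_table(n=200, seed=3)
    table.loc[: len(table) // 2, "connectivity"] = "S_Fam"
    fm = fit_forest(table, grid=(10,), rng=0)
    assert len(fm.X_train) + len(fm.X_test) == (table["connectivity"] == "S_All").sum()


# ---------------------------------------------------------------------------
# gini and permutation importance
# ---------------------------------------------------------------------------

def test_gini_scores_are_a_distribution(planted_forest):
    _, fm = planted_forest
    g = gini_importance(fm)
    assert (g >= 0).all()
    assert g.sum() == pytest.approx(1.0)
    assert g.idxmax() == "Qual"


def test_single_informative_feature_takes_all_importance():
    table = synthetic_presence_table(n=500, effects={"Yield": 2.0}, noise_sd=0.0, seed=4)
    fm = fit_forest(table, grid=(20,), rng=1)
    g = gini_importance(fm)
    assert g["Yield"] > 0.95
    perm = permutation_importance(fm, repeats=5, rng=1)
    others = perm["mean"].drop("Yield").abs()
    assert perm.loc["Yield", "mean"] > 0
    assert (others < 1e-2 * perm.loc["Yield", "mean"]).all()


def test_constant_target_has_no_importance():
    table = synthetic_presence_table(n=300, effects={}, noise_sd=0.0, seed=5)
    table["fitness"] = 7.0
    fm = fit_forest(table, grid=(10,), rng=0)
    perm = permutation_importance(fm, repeats=5, rng=0)
    np.testing.assert_allclose(perm["mean"], 0.0, atol=1e-12)


def test_uninformative_feature_importance_within_noise(planted_forest):
    """A feature independent of the target has |mean| < 2 sd importance."""
    _, fm = planted_forest
    perm = permutation_importance(fm, repeats=10, rng=3)
    for f in ("Dry", "Water", "HAge"):  # no planted effect
        assert abs(perm.loc[f, "mean"]) < 2 * perm.loc[f, "sd"] + 1e-12


def test_permutation_requires_two_repeats(planted_forest):
    _, fm = planted_forest
    with pytest.raises(ValueError):
        permutation_importance(fm, repeats=1, rng=0)


# ---------------------------------------------------------------------------
# joint contributions
# ---------------------------------------------------------------------------

def _manual_forest(X, y, **kw):
    model = RandomForestRegressor(random_state=0, bootstrap=False, **kw)
    model.fit(X, y)
    return ForestModel(model, kw.get("n_estimators", 100), 1.0, X, X, y, y)


def test_depth_one_tree_attributes_the_split_to_its_feature():
    """Root mean 15, leaves 10/20 split on Qual: a right-routed sample gets
    contribution {Qual}: +5 and reconstruction bias + 5 = 20."""
    X = np.zeros((10, 9))
    X[5:, FACTORS.index("Qual")] = 1.0
    y = np.array([10.0] * 5 + [20.0] * 5)
    fm = _manual_forest(X, y, n_estimators=1, max_depth=1)
    bias, contrib = decompose_forest(fm, X)
    assert bias == pytest.approx(15.0)
    assert set(contrib) == {frozenset({"Qual"})}
    np.testing.assert_allclose(contrib[frozenset({"Qual"})], [-5.0] * 5 + [5.0] * 5)


def test_decomposition_reconstructs_predictions_exactly(planted_forest):
    table, fm = planted_forest
    X = fm.X_test
    bias, contrib = decompose_forest(fm, X)
    total = bias + sum(contrib.values())
    np.testing.assert_allclose(total, fm.model.predict(X), rtol=1e-9)


def test_joint_report_is_normalized_and_capped_at_triples(planted_forest):
    _, fm = planted_forest
    report = joint_contributions(fm)
    assert report.scores.sum() == pytest.approx(1.0)
    assert (report.scores >= 0).all()
    assert max(len(k) for k in report.scores.index) <= 3


def test_pure_interaction_surfaces_as_a_pair():
    table = synthetic_presence_table(
        n=2000, effects={}, interaction=("Qual", "Mig", 20.0), noise_sd=1.0, seed=8
    )
    fm = fit_forest(table, grid=(60,), rng=2, max_depth=6)
    report = joint_contributions(fm)
    assert ("Qual", "Mig") in set(report.top(3).index)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def enumeration_pvalue(a, b):
    """Exact one-tailed (less) p by enumerating all group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)

    # U counts pairs with x from the first group exceeding y (tie half-credit)
    def u_of(xs, ys):
        return sum(1.0 if y < x else 0.5 if x == y else 0.0 for x in xs for y in ys)

    observed = u_of(a, b)
    count = total = 0
    for chosen in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        total += 1
        if u_of(xs, ys) <= observed + 1e-12:
            count += 1
    return count / total


def test_textbook_exact_cases():
    u, p = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
    assert p == pytest.approx(0.05)
    _, p = mann_whitney([5], [1], alternative="less")
    assert p == pytest.approx(1.0)


def test_exact_pvalues_agree_with_enumeration():
    rng = np.random.default_rng(17)
    for n_a in range(1, 5):
        for n_b in range(1, 5):
            vals = rng.permutation(np.arange(1.0, n_a + n_b + 1))  # tie-free
            a, b = vals[:n_a], vals[n_a:]
            _, p = mann_whitney(a, b, alternative="less")
            assert p == pytest.approx(enumeration_pvalue(a, b)), (a, b)


def test_identical_data_short_circuits_to_p_one():
    u, p = mann_whitney([3.0, 3.0], [3.0, 3.0, 3.0])
    assert p == 1.0 and np.isfinite(u)


def test_matrix_decisions_are_antisymmetric():
    rng = np.random.default_rng(2)
    groups = {
        "lo": rng.normal(0, 1, 40),
        "mid": rng.normal(1, 1, 40),
        "hi": rng.normal(3, 1, 40),
    }
    cm = mann_whitney_matrix(groups, alternative="less")
    assert np.isnan(cm.p.loc["lo", "lo"])
    for a, b in itertools.permutations(groups, 2):
        assert not (cm.reject.loc[a, b] and cm.reject.loc[b, a])
    assert cm.reject.loc["lo", "hi"] and not cm.reject.loc["hi", "lo"]


# ---------------------------------------------------------------------------
# presence summaries
# ---------------------------------------------------------------------------

def _presence_table(counts_by_value, factor="Qual", fitness_by_value=None):
    rows = []
    for v, n in counts_by_value.items():
        for i in range(n):
            fit = fitness_by_value[v][i] if fitness_by_value else float(i)
            row = dict.fromkeys(FACTORS, 0)
            row[factor] = v
            row.update(connectivity="S_All", fitness=fit, run=0, generation=0)
            rows.append(row)
    return pd.DataFrame(rows)


def test_presence_values_below_min_count_are_excluded():
    table = _presence_table({0: 199, 1: 200})
    summary, _ = presence_fitness_summary(table, min_count=200)
    qual = summary[summary["factor"] == "Qual"]
    assert list(qual["presence"]) == [1]


def test_summary_medians_match_manual_tabulation():
    fitness = {0: [10.0, 12.0, 14.0], 1: [1.0, 2.0, 9.0], 2: [5.0, 5.0, 8.0]}
    table = _presence_table({v: 3 for v in fitness}, fitness_by_value=fitness)
    summary, matrices = presence_fitness_summary(table, min_count=3)
    qual = summary[summary["factor"] == "Qual"].set_index("presence")
    assert qual.loc[0, "median"] == 12.0
    assert qual.loc[1, "median"] == 2.0
    assert qual.loc[2, "median"] == 5.0
    assert qual.loc[1, "q1"] == 1.5 and qual.loc[1, "q3"] == 5.5
    assert "Qual" in matrices and matrices["Qual"].p.shape == (3, 3)


def test_single_presence_value_yields_one_row_and_no_matrix():
    table = _presence_table({1: 5})
    summary, matrices = presence_fitness_summary(table, min_count=3)
    assert len(summary[summary["factor"] == "Qual"]) == 1
    assert "Qual" not in matrices


# ---------------------------------------------------------------------------
# strategy comparison
# ---------------------------------------------------------------------------

def test_single_run_refuses_tests(small_env):
    res = compare_strategies(
        ["argmax[S_All](F_Qual)"], small_env, n_runs=1, rng=0
    )
    assert res.tests is None and "2 runs" in res.message
    assert len(res.distributions) == 2


def test_equivalent_strategy_null_is_calibrated(small_env):
    """Comparing a strategy against a decision-equivalent rewrite of itself
    should rarely reject."""
    rejections = 0
    for seed in range(8):
        res = compare_strategies(
            ["argmax[S_All](F_Qual)"], small_env, n_runs=15,
            baseline="argmax[S_All](2*F_Qual)", rng=seed,
        )
        rejections += int(res.tests.iloc[0]["significant"])
    assert rejections <= 1
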