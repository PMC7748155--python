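"""Factor sub-scores, candidate subsets, rule evaluation, presence, grammar."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from emdisc.gp import _random_tree
from emdisc.rules import (
    CONNECTIVITIES,
    FACTORS,
    BinOp,
    FactorConfig,
    RuleParseError,
    RuleTree,
    SIGNATURES,
    Terminal,
    candidate_subset,
    check_types,
    evaluate_rule,
    evaluate_tree,
    extract_presence,
    factor_subscore,
    factor_subscores,
    format_rule,
    parse_rule,
)

from conftest import make_context, make_landscape, random_context


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_choice(rule, ctx):
    """Independent argmax: score candidates one by one with scalar arithmetic
    in the canonical factor order, track the best with the (y, x) tie-break."""
    coeffs = extract_presence(rule)
    subs = {f: factor_subscores(f, ctx) for f in FACTORS if coeffs[f]}
    best = None
    for i, (x, y) in enumerate(ctx.candidates):
        val = 0.0
        for name in FACTORS:
            if coeffs[name]:
                val = val + coeffs[name] * subs[name][i]
        key = (-val, y, x)
        if best is None or key < best:
            best = key
    return (int(best[2]), int(best[1])) if best is not None else None


def scalar_tree_value(node, i, ctx):
    if isinstance(node, Terminal):
        return float(factor_subscores(node.name, ctx)[i])
    l = scalar_tree_value(node.left, i, ctx)
    r = scalar_tree_value(node.right, i, ctx)
    return l + r if node.op == "+" else l - r


def sympy_presence(node):
    """Symbolic-expansion oracle for presence extraction."""
    syms = {f: sympy.Symbol(f) for f in FACTORS}

    def to_expr(n):
        if isinstance(n, Terminal):
            return syms[n.name]
        a, b = to_expr(n.left), to_expr(n.right)
        return a + b if n.op == "+" else a - b

    expanded = sympy.expand(to_expr(node))
    return {f: int(expanded.coeff(syms[f])) for f in FACTORS}


def random_rule(rng, min_depth=1, max_depth=6):
    root = _random_tree(rng, min_depth, max_depth, full=bool(rng.integers(2)))
    return RuleTree(CONNECTIVITIES[rng.integers(4)], root)


# ---------------------------------------------------------------------------
# factor sub-scores
# ---------------------------------------------------------------------------

def test_quality_subscores_are_minmax_normalized():
    ls = make_landscape([[0.2, 0.5, 0.8]])
    ctx = make_context(ls, [(0, 0), (1, 0), (2, 0)])
    np.testing.assert_allclose(factor_subscores("Qual", ctx), [0.0, 0.5, 1.0])
    assert factor_subscore("Qual", (1, 0), ctx) == pytest.approx(0.5)


def test_migration_subscore_is_binary_without_normalization():
    ls = make_landscape([[0.5, 0.5, 0.5]], zone=[[0, 0, 1]])
    ctx = make_context(ls, [(0, 0), (1, 0), (2, 0)], ref_zone=0)
    np.testing.assert_array_equal(factor_subscores("Mig", ctx), [0.0, 0.0, 1.0])


def test_social_presence_counts_nearby_households():
    ls = make_landscape(np.full((8, 8), 0.5))
    households = [(i, (1, 1), 10.0, 50.0) for i in range(3)]  # 3 near plot A=(0,0)
    ctx = make_context(
        ls, [(0, 0), (7, 7)], households=households, config=FactorConfig(social_radius=2)
    )
    np.testing.assert_allclose(factor_subscores("Soc", ctx), [1.0, 0.0])


def test_degenerate_normalization_scores_half():
    ls = make_landscape(np.full((1, 3), 0.7))
    ctx = make_context(ls, [(0, 0), (1, 0), (2, 0)])
    np.testing.assert_allclose(factor_subscores("Qual", ctx), [0.5, 0.5, 0.5])


def test_distance_orientation_flips_with_config():
    ls = make_landscape(np.full((1, 3), 0.5))
    far = make_context(ls, [(1, 0), (2, 0)], ref_farm=(0, 0))
    np.testing.assert_allclose(factor_subscores("Dist", far), [0.0, 1.0])
    near = make_context(
        ls, [(1, 0), (2, 0)], ref_farm=(0, 0),
        config=FactorConfig(dist_farther_is_better=False),
    )
    np.testing.assert_allclose(factor_subscores("Dist", near), [1.0, 0.0])


def test_all_subscores_lie_in_unit_interval_on_fuzzed_contexts():
    rng = np.random.default_rng(7)
    for _ in range(300):
        ctx = random_context(rng)
        for f in FACTORS:
            s = factor_subscores(f, ctx)
            assert s.shape == (len(ctx.candidates),)
            assert np.all((s >= 0.0) & (s <= 1.0)), f


# ---------------------------------------------------------------------------
# candidate subsets
# ---------------------------------------------------------------------------

def test_full_information_admits_every_available_plot():
    ls = make_landscape(np.full((2, 2), 0.5))
    available = np.array([[True, True], [True, False]])
    ctx = make_context(ls, [(0, 0)], available=available)
    got = {tuple(p) for p in candidate_subset("S_All", ctx)}
    assert got == {(0, 0), (1, 0), (0, 1)}


def test_family_knowledge_defaults_to_self():
    ls = make_landscape(np.full((9, 9), 0.5))
    ctx = make_context(
        ls, [(0, 0)], ref_dwelling=(4, 4),
        households=[(5, (0, 8), 10.0, 1.0)],  # unrelated household far away
        decider_id=0,
        config=FactorConfig(neighbor_radius=2),
    )
    ctx.family_ids = frozenset({0})
    got = {tuple(p) for p in candidate_subset("S_Fam", ctx)}
    assert got  # knows its own surroundings
    assert all((x - 4) ** 2 + (y - 4) ** 2 <= 4 for x, y in got)


def test_best_performer_knowledge_matches_brute_force_top_k():
    ls = make_landscape(np.full((9, 9), 0.5))
    households = [(0, (0, 0), 10.0, 5.0), (1, (8, 0), 10.0, 9.0), (2, (0, 8), 10.0, 1.0)]
    cfg = FactorConfig(neighbor_radius=2, top_k=2)
    ctx = make_context(
        ls, [(0, 0)], ref_dwelling=(4, 4), households=households, decider_id=0, config=cfg
    )
    got = {tuple(p) for p in candidate_subset("S_Perf", ctx)}

    # Brute force: plots known to the stock-9 and stock-5 households (+ self).
    tops = [(0, 0), (8, 0), (4, 4)]
    brute = {
        (x, y)
        for y in range(9)
        for x in range(9)
        if any((x - dx) ** 2 + (y - dy) ** 2 <= 4 for dx, dy in tops)
    }
    assert got == brute


# ---------------------------------------------------------------------------
# rule evaluation
# ---------------------------------------------------------------------------

def test_negated_distance_selects_nearest_plot():
    ls = make_landscape(np.full((1, 4), 0.5))
    rule = parse_rule("argmax[S_All](-F_Dist)")
    ctx = make_context(ls, [(1, 0), (2, 0), (3, 0)], ref_farm=(0, 0))
    assert evaluate_rule(rule, ctx) == (1, 0)


def test_forced_tie_breaks_on_lowest_y_then_x():
    ls = make_landscape(np.full((2, 2), 0.5))
    rule = parse_rule("argmax[S_All](F_Mig)")  # single zone: every score 0
    ctx = make_context(ls, [(1, 1), (0, 1), (1, 0)], ref_zone=0)
    assert evaluate_rule(rule, ctx) == (1, 0)


def test_empty_candidate_set_returns_none():
    ls = make_landscape(np.full((1, 2), 0.5))
    ctx = make_context(ls, np.empty((0, 2), dtype=int))
    assert evaluate_rule(parse_rule("argmax[S_All](F_Qual)"), ctx) is None


def test_composite_rule_matches_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    ls = make_landscape(rng.random((3, 5)))
    rule = parse_rule("argmax[S_All](F_Qual + F_Soc)")
    households = [(i, (int(rng.integers(5)), int(rng.integers(3))), 5.0, 10.0) for i in range(4)]
    ctx = make_context(ls, [(0, 0), (1, 0), (2, 1), (3, 2), (4, 2)], households=households)
    assert evaluate_rule(rule, ctx) == brute_force_choice(rule, ctx)


def test_evaluation_matches_brute_force_on_fuzzed_contexts():
    rng = np.random.default_rng(123)
    for _ in range(300):
        ctx = random_context(rng)
        rule = random_rule(rng)
        assert evaluate_rule(rule, ctx) == brute_force_choice(rule, ctx)


def test_linear_scores_equal_tree_recursion():
    """The linear-expansion fast path is numerically the expression tree."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        ctx = random_context(rng)
        rule = random_rule(rng, max_depth=5)
        vec = evaluate_tree(rule.root, ctx)
        for i in range(len(ctx.candidates)):
            assert scalar_tree_value(rule.root, i, ctx) == pytest.approx(vec[i], abs=1e-9)


# ---------------------------------------------------------------------------
# presence extraction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,expected",
    [
        ("argmax[S_All](-F_Dist - F_Dry + 2*F_Mig)", {"Dist": -1, "Dry": -1, "Mig": 2}),
        ("argmax[S_All](F_Qual)", {"Qual": 1}),
        (
            "argmax[S_All](F_Dist + F_Qual + 2*F_Yield + F_Soc + F_HAgri + 2*F_Mig)",
            {"Dist": 1, "Qual": 1, "Yield": 2, "Soc": 1, "HAgri": 1, "Mig": 2},
        ),
    ],
)
def test_presence_of_published_rule_forms(text, expected):
    presence = extract_presence(parse_rule(text))
    assert presence == {f: expected.get(f, 0) for f in FACTORS}


def test_presence_of_nested_subtraction():
    tree = BinOp("-", Terminal("Soc"), BinOp("-", Terminal("Dist"), Terminal("Soc")))
    presence = extract_presence(tree)
    assert presence["Soc"] == 2 and presence["Dist"] == -1
    assert sympy_presence(tree) == presence


def test_presence_matches_symbolic_expansion_on_random_trees():
    rng = np.random.default_rng(99)
    for _ in range(200):
        rule = random_rule(rng)
        assert extract_presence(rule) == sympy_presence(rule.root)


# ---------------------------------------------------------------------------
# grammar
# ---------------------------------------------------------------------------

def test_parse_format_round_trip_is_canonicalization():
    t = "argmax[S_All](F_Qual + F_Mig + F_Soc)"
    rule = parse_rule(t)
    assert extract_presence(rule) == {
        f: (1 if f in ("Qual", "Mig", "Soc") else 0) for f in FACTORS
    }
    assert format_rule(rule) == "argmax[S_All](F_Qual + F_Soc + F_Mig)"
    # Canonical strings are fixed points.
    assert format_rule(parse_rule(format_rule(rule))) == format_rule(rule)


@pytest.mark.parametrize(
    "bad", ["argmax[S_All](F_Bogus)", "argmax[S_Everyone](F_Qual)", "F_Qual + F_Mig"]
)
def test_parse_rejects_unknown_tokens(bad):
    with pytest.raises(RuleParseError):
        parse_rule(bad)


def test_zero_rule_round_trips():
    rule = parse_rule("argmax[S_All](F_Qual - F_Qual)")
    assert format_rule(rule) == "argmax[S_All](0)"
    assert extract_presence(parse_rule("argmax[S_All](0)")) == dict.fromkeys(FACTORS, 0)


# ---------------------------------------------------------------------------
# typing
# ---------------------------------------------------------------------------

def test_generated_trees_satisfy_type_condition():
    rng = np.random.default_rng(4)
    for _ in range(100):
        assert check_types(random_rule(rng).root) == "score"


def test_ill_formed_nodes_unrepresentable():
    with pytest.raises(ValueError):
        Terminal("Bogus")
    with pytest.raises(ValueError):
        BinOp("*", Terminal("Qual"), Terminal("Soc"))
    with pytest.raises(ValueError):
        RuleTree("S_Everyone", Terminal("Qual"))


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=50, deadline=None)
def test_signature_arity_and_terminal_invariants(seed):
    rng = np.random.default_rng(seed)
    rule = random_rule(rng, max_depth=4)
    for name, sig in SIGNATURES.items():
        assert sig.arity == len(sig.param_types)
    # every terminal in the tree is a declared arity-0 factor
    stack = [rule.root]
    while stack:
        n = stack.pop()
        if isinstance(n, Terminal):
            assert SIGNATURES[n.name].arity == 0
        else:
            stack += [n.left, n.right]
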