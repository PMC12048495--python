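import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from suipath import (
    BranchRule,
    PathQuery,
    assign_paths,
    compare_cure_rates,
    constrained_shortest_path,
    natural_cure_estimate,
    shortest_path,
)
from suipath.network import VarNetwork

from conftest import brute_force_shortest, make_random_graph


def _net(edges):
    import networkx as nx

    G = nx.Graph()
    for a, b, w in edges:
        G.add_edge(a, b, weight=w, r=1.0 / w)
    return VarNetwork(graph=G)


# ---------------------------------------------------------------------------
# shortest path

def test_triangle_forced_by_weights():
    net = _net([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 3.0)])
    res = shortest_path(net, "a", "c")
    assert res.nodes == ("a", "b", "c")
    assert res.total_weight == pytest.approx(2.0)


def test_disconnected_is_infeasible():
    net = _net([("a", "b", 1.0), ("c", "d", 1.0)])
    res = shortest_path(net, "a", "d")
    assert not res.feasible
    assert res.nodes == ()


def test_unknown_node_raises_naming_it():
    net = _net([("a", "b", 1.0)])
    with pytest.raises(ValueError, match="zz"):
        shortest_path(net, "a", "zz")


def test_equal_weight_tie_breaks_lexicographically():
    # two equal-weight routes a->b->d and a->c->d: the 'b' route must win
    net = _net([("a", "b", 1.0), ("b", "d", 1.0), ("a", "c", 1.0), ("c", "d", 1.0)])
    res = shortest_path(net, "a", "d")
    assert res.nodes == ("a", "b", "d")


@pytest.mark.parametrize("seed", range(50))
def test_dijkstra_agrees_with_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    G = make_random_graph(rng, n_nodes=8, p_edge=0.45)
    res = shortest_path(VarNetwork(graph=G), "a", "h")
    oracle = brute_force_shortest(G, "a", "h")
    if oracle is None:
        assert not res.feasible
    else:
        assert res.feasible
        assert res.total_weight == pytest.approx(oracle[0])
        assert res.nodes == oracle[1]


# ---------------------------------------------------------------------------
# constrained paths

def test_empty_constraints_reduce_to_shortest_path():
    net = _net([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 3.0)])
    q = PathQuery(source="a", target="c")
    assert constrained_shortest_path(net, q) == shortest_path(net, "a", "c")


def test_required_node_already_on_path_changes_nothing():
    net = _net([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 3.0)])
    q = PathQuery(source="a", target="c", required=("b",))
    res = constrained_shortest_path(net, q)
    assert res.nodes == ("a", "b", "c")
    assert res.total_weight == pytest.approx(2.0)


@pytest.mark.parametrize("seed", range(25))
def test_constrained_path_agrees_with_enumeration_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    G = make_random_graph(rng, n_nodes=8, p_edge=0.5)
    res = constrained_shortest_path(
        VarNetwork(graph=G), PathQuery(source="a", target="h", required=("d",))
    )
    oracle = brute_force_shortest(G, "a", "h", must_contain="d")
    if oracle is None:
        # segment concatenation may still find a revisiting walk where no
        # simple path exists; only compare when the result is simple
        if res.feasible:
            assert res.revisits
    elif res.feasible and not res.revisits:
        assert res.total_weight == pytest.approx(oracle[0])


def test_forbidden_node_is_avoided():
    net = _net([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 3.0)])
    q = PathQuery(source="a", target="c", forbidden=frozenset({"b"}))
    res = constrained_shortest_path(net, q)
    assert res.nodes == ("a", "c")
    assert res.total_weight == pytest.approx(3.0)


def test_required_node_absent_is_infeasible_with_reason():
    net = _net([("a", "b", 1.0)])
    q = PathQuery(source="a", target="b", required=("zz",))
    res = constrained_shortest_path(net, q)
    assert not res.feasible
    assert "zz" in res.reason


@pytest.mark.parametrize("seed", range(10))
def test_required_node_never_shortens_path(seed):
    rng = np.random.default_rng(2000 + seed)
    G = make_random_graph(rng, n_nodes=7, p_edge=0.6)
    base = shortest_path(VarNetwork(graph=G), "a", "g")
    cons = constrained_shortest_path(
        VarNetwork(graph=G), PathQuery(source="a", target="g", required=("d",))
    )
    if base.feasible and cons.feasible:
        assert cons.total_weight >= base.total_weight - 1e-12


def test_query_validation():
    with pytest.raises(ValueError, match="differ"):
        PathQuery(source="a", target="a")
    with pytest.raises(ValueError, match="overlap"):
        PathQuery(source="a", target="b", required=("c",), forbidden=frozenset({"c"}))
    with pytest.raises(ValueError, match="forbidden"):
        PathQuery(source="a", target="b", forbidden=frozenset({"a"}))


# ---------------------------------------------------------------------------
# patient stratification

def _line_net():
    # ap - av - bi - bj backbone with a detour through af
    return _net(
        [("ap", "av", 1.0), ("av", "bi", 1.0), ("bi", "bj", 1.0),
         ("av", "af", 1.5), ("af", "bi", 1.5)]
    )


def test_no_rules_gives_single_stratum():
    df = pd.DataFrame({"b": [1.0, 2.0, 3.0, 4.0], "bi": [1, 0, 1, 1]})
    strata = assign_paths(df, _line_net(), milestones=("ap", "av", "bi", "bj"))
    assert len(strata) == 1
    assert strata[0].proportion == 1.0
    assert strata[0].n == 4
    assert strata[0].cure_rate == pytest.approx(0.75)


def test_branch_rule_quantile_controls_stratum_proportion():
    # exactly 10% of patients exceed the mean cutoff by construction
    b = np.zeros(100)
    b[:10] = 10.0   # mean = 1.0; the ten 10s exceed it, the 0s do not
    df = pd.DataFrame({"b": b, "bi": np.ones(100, dtype=int)})
    rules = [BranchRule(variable="b", op="gt_mean", insert_node="af")]
    strata = assign_paths(df, _line_net(), milestones=("ap", "av", "bi", "bj"),
                          branch_rules=rules)
    by_label = {s.path_label: s for s in strata}
    af_stratum = next(s for s in strata if "af" in s.nodes)
    assert af_stratum.proportion == pytest.approx(0.10)
    assert sum(s.proportion for s in strata) == pytest.approx(1.0)


def test_mutually_exclusive_rules_partition_cohort():
    df = pd.DataFrame({"x": [0.0, 0.0, 1.0, 1.0], "bi": [0, 1, 1, 1]})
    net = _net(
        [("ap", "av", 1.0), ("av", "bi", 1.0), ("bi", "bj", 1.0),
         ("av", "af", 1.0), ("af", "bi", 1.0), ("av", "q", 1.0), ("q", "bi", 1.0)]
    )
    rules = [
        BranchRule(variable="x", op="eq", value=1.0, insert_node="af"),
        BranchRule(variable="x", op="eq", value=0.0, insert_node="q"),
    ]
    strata = assign_paths(df, net, milestones=("ap", "av", "bi", "bj"), branch_rules=rules)
    assert sum(s.proportion for s in strata) == pytest.approx(1.0)
    assert len(strata) == 2


def test_rule_referencing_absent_node_errors():
    df = pd.DataFrame({"b": [1.0], "bi": [1]})
    rules = [BranchRule(variable="b", op="gt_mean", insert_node="zz")]
    with pytest.raises(ValueError, match="zz"):
        assign_paths(df, _line_net(), milestones=("ap", "av", "bi", "bj"),
                     branch_rules=rules)


# ---------------------------------------------------------------------------
# cure-rate arithmetic

def test_natural_cure_worked_example():
    est = natural_cure_estimate(0.2889, 23)
    assert est.expected_cures == 6.64
    assert est.proportion_pct == 28.87


@pytest.mark.parametrize("rate,n,cures,pct", [(0.0, 50, 0.0, 0.0), (1.0, 7, 7.0, 100.0)])
def test_natural_cure_degenerate_rates(rate, n, cures, pct):
    est = natural_cure_estimate(rate, n)
    assert est.expected_cures == cures
    assert est.proportion_pct == pct


def test_natural_cure_rejects_bad_inputs():
    with pytest.raises(ValueError):
        natural_cure_estimate(1.2, 10)
    with pytest.raises(ValueError):
        natural_cure_estimate(0.5, 0)


@settings(max_examples=200, derandomize=True)
@given(rate=st.floats(0.0, 1.0), n=st.integers(1, 500))
def test_natural_cure_rounding_stays_within_half_point(rate, n):
    est = natural_cure_estimate(rate, n)
    target = round(100.0 * rate, 2)
    assert target - 0.5 <= est.proportion_pct <= target + 0.5


def test_exact_binomial_tail_closed_form():
    # 3/3 cured against a control rate of 1/2: upper tail = 0.5^3
    _, p_exact, _ = compare_cure_rates(3, 3, 45, 90)
    assert p_exact == pytest.approx(0.125)


def test_equal_rates_give_zero_z():
    z, _, p_normal = compare_cure_rates(30, 60, 30, 60)
    assert z == pytest.approx(0.0)
    assert p_normal == pytest.approx(1.0)


def test_pooled_z_matches_independent_formula():
    k1, n1, k2, n2 = 21, 23, 26, 90
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    z_ref = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z, _, _ = compare_cure_rates(k1, n1, k2, n2)
    assert z == pytest.approx(z_ref, rel=1e-12)


def test_empty_control_group_errors():
    with pytest.raises(ValueError, match="control"):
        compare_cure_rates(1, 2, 0, 0)
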