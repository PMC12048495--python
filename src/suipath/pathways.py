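"""Shortest-path treatment-pathway analysis.

On the inverse-correlation network, a short path is a chain of strongly
associated variables, read clinically as a plausible progression from the
initial assessment to return to elite competition.  This module provides
Dijkstra shortest paths with a deterministic lexicographic tie-break,
waypoint-constrained paths (required / forbidden nodes), severity branch
rules that stratify patients by the path their profile implies, cure-rate
arithmetic per stratum, the natural-cure estimate, and binomial cure-rate
comparisons.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MILESTONES
from .network import VarNetwork
from .simulate import Cohort

__all__ = [
    "PathQuery",
    "PathResult",
    "StratumReport",
    "NaturalCureEstimate",
    "BranchRule",
    "shortest_path",
    "constrained_shortest_path",
    "assign_paths",
    "natural_cure_estimate",
    "compare_cure_rates",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PathQuery:
    source: str
    target: str
    required: tuple[str, ...] = ()
    forbidden: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target must differ")
        req = set(self.required)
        if req & set(self.forbidden):
            raise ValueError("required and forbidden sets overlap")
        if {self.source, self.target} & set(self.forbidden):
            raise ValueError("source/target cannot be forbidden")


@dataclass
class PathResult:
    nodes: tuple[str, ...]
    total_weight: float
    feasible: bool
    revisits: bool = False
    reason: str = ""

    @property
    def label(self) -> str:
        return " -> ".join(self.nodes) if self.feasible else "(infeasible)"


@dataclass
class StratumReport:
    path_label: str
    nodes: tuple[str, ...]
    n: int
    proportion: float
    cure_rate: float


@dataclass
class NaturalCureEstimate:
    """Expected spontaneous cures in a group, at the control-arm natural rate.

    ``expected_cures`` is rounded to 2 dp *before* the percentage is formed,
    so ``proportion_pct`` can differ slightly from 100 × natural_rate."""

    natural_rate: float
    n_group: int
    expected_cures: float
    proportion_pct: float


@dataclass(frozen=True)
class BranchRule:
    """If ``predicate(variable value, cohort)`` holds, insert ``insert_node``
    into the patient's required waypoints.  ``op`` ∈ {gt_mean, gt, eq}."""

    variable: str
    op: str
    insert_node: str
    value: float | None = None

    def matches(self, x: pd.Series, cohort_col: pd.Series) -> pd.Series:
        if self.op == "gt_mean":
            return x > cohort_col.mean()
        if self.op == "gt":
            return x > self.value
        if self.op == "eq":
            return x == self.value
        raise ValueError(f"unknown rule op {self.op!r}")


def _graph(net: VarNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, VarNetwork) else net


def _dijkstra_lex(G: nx.Graph, source: str, target: str) -> PathResult:
    """Dijkstra with lexicographically-smallest tie-break on equal weight.

    The heap is ordered by (distance, node sequence); on (near-)ties both
    candidates stay in the heap, so the first time the target pops, its path
    is the minimum-weight, lexicographically-smallest one.
    """
    best: dict[str, float] = {source: 0.0}
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    while heap:
        d, path = heapq.heappop(heap)
        node = path[-1]
        if node == target:
            return PathResult(nodes=path, total_weight=d, feasible=True)
        if d > best.get(node, np.inf) + _EPS:
            continue
        for nbr, attrs in G[node].items():
            w = attrs.get("weight", 1.0)
            if w <= 0:
                raise ValueError(f"non-positive edge weight on ({node}, {nbr})")
            nd = d + w
            if nd < best.get(nbr, np.inf) - _EPS:
                best[nbr] = nd
                heapq.heappush(heap, (nd, path + (nbr,)))
            elif nd <= best.get(nbr, np.inf) + _EPS and nbr not in path:
                heapq.heappush(heap, (nd, path + (nbr,)))
    return PathResult(nodes=(), total_weight=np.inf, feasible=False, reason="disconnected")


def shortest_path(net: VarNetwork | nx.Graph, source: str, target: str) -> PathResult:
    """Minimum-total-weight path; deterministic under equal-weight ties."""
    G = _graph(net)
    for code in (source, target):
        if code not in G:
            raise ValueError(f"unknown node {code!r}")
    if source == target:
        raise ValueError("source and target must differ")
    return _dijkstra_lex(G, source, target)


def constrained_shortest_path(net: VarNetwork | nx.Graph, q: PathQuery) -> PathResult:
    """Shortest path through a set of required waypoints, avoiding forbidden nodes.

    Forbidden nodes are removed up front.  For every permutation of the
    required nodes (|required| ≤ 4) the segment-wise shortest paths
    source → r1 → … → target are concatenated; the minimal total weight wins,
    with the lexicographic node-sequence tie-break.  Nodes revisited across
    segments are permitted but flagged via ``revisits``.
    """
    G = _graph(net).copy()
    if len(q.required) > 4:
        raise ValueError("at most 4 required nodes supported")
    for code in q.forbidden:
        if code in G:
            G.remove_node(code)
    for code in (q.source, q.target):
        if code not in G:
            return PathResult((), np.inf, False, reason=f"node {code!r} absent from graph")
    missing = [c for c in q.required if c not in G]
    if missing:
        return PathResult((), np.inf, False, reason=f"required node(s) absent: {missing}")
    if not q.required:
        return _dijkstra_lex(G, q.source, q.target)
    best: PathResult | None = None
    for perm in itertools.permutations(q.required):
        waypoints = (q.source, *perm, q.target)
        nodes: tuple[str, ...] = (q.source,)
        total = 0.0
        ok = True
        for a, b in zip(waypoints, waypoints[1:]):
            if a == b:
                continue
            seg = _dijkstra_lex(G, a, b)
            if not seg.feasible:
                ok = False
                break
            nodes = nodes + seg.nodes[1:]
            total += seg.total_weight
        if not ok:
            continue
        cand = PathResult(
            nodes=nodes, total_weight=total, feasible=True,
            revisits=len(set(nodes)) < len(nodes),
        )
        if (
            best is None
            or cand.total_weight < best.total_weight - _EPS
            or (abs(cand.total_weight - best.total_weight) <= _EPS and cand.nodes < best.nodes)
        ):
            best = cand
    if best is None:
        return PathResult((), np.inf, False, reason="required nodes unreachable")
    return best


def assign_paths(
    cohort: Cohort | pd.DataFrame,
    net: VarNetwork | nx.Graph,
    milestones: Sequence[str] = MILESTONES,
    branch_rules: Sequence[BranchRule] = (),
    cure_code: str = "bi",
) -> list[StratumReport]:
    """Stratify patients by the constrained path their profile implies.

    The milestone sequence fixes source, target and always-required interior
    waypoints.  Each branch rule whose predicate holds for a patient inserts
    its node into that patient's required set.  Patients are grouped by the
    resulting path node sequence; each stratum reports its size, proportion
    of the whole cohort, and cure rate (mean of ``cure_code``).
    """
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    G = _graph(net)
    if len(milestones) < 2:
        raise ValueError("need at least source and target milestones")
    source, *middle, target = milestones
    for rule in branch_rules:
        if rule.variable not in df.columns:
            raise ValueError(f"branch rule variable {rule.variable!r} not in cohort")
        if rule.insert_node not in G:
            raise ValueError(f"branch rule inserts pruned/absent node {rule.insert_node!r}")
    matches = [rule.matches(df[rule.variable], df[rule.variable]) for rule in branch_rules]
    path_cache: dict[tuple[str, ...], PathResult] = {}
    assignment: dict[int, tuple[str, ...]] = {}
    for idx in df.index:
        required = list(middle)
        for rule, m in zip(branch_rules, matches):
            if bool(m.loc[idx]) and rule.insert_node not in required:
                required.append(rule.insert_node)
        key = tuple(required)
        if key not in path_cache:
            path_cache[key] = constrained_shortest_path(
                G, PathQuery(source=source, target=target, required=key)
            )
        res = path_cache[key]
        assignment[idx] = res.nodes if res.feasible else ("(infeasible)",)
    total = len(df)
    strata: list[StratumReport] = []
    groups: dict[tuple[str, ...], list[int]] = {}
    for idx, nodes in assignment.items():
        groups.setdefault(nodes, []).append(idx)
    for nodes, ids in sorted(groups.items()):
        sub = df.loc[ids]
        cure = float(sub[cure_code].mean()) if cure_code in df.columns else float("nan")
        strata.append(
            StratumReport(
                path_label=" -> ".join(nodes), nodes=nodes, n=len(ids),
                proportion=len(ids) / total, cure_rate=cure,
            )
        )
    return strata


def natural_cure_estimate(natural_rate: float, n_group: int) -> NaturalCureEstimate:
    """Expected spontaneous cures: round(rate × n, 2), then the percentage of
    the group that represents, rounded to 2 dp (round-then-divide order)."""
    if not 0.0 <= natural_rate <= 1.0:
        raise ValueError(f"natural_rate {natural_rate} outside [0, 1]")
    if n_group < 1:
        raise ValueError("n_group must be >= 1")
    expected = round(natural_rate * n_group, 2)
    pct = round(100.0 * expected / n_group, 2)
    return NaturalCureEstimate(
        natural_rate=natural_rate, n_group=n_group,
        expected_cures=expected, proportion_pct=pct,
    )


def compare_cure_rates(
    k_treat: int, n_treat: int, k_ctrl: int, n_ctrl: int
) -> tuple[float, float, float]:
    """Compare two cure proportions.

    Returns ``(z_stat, p_exact, p_normal)``: the pooled two-proportion z
    statistic (sign convention: treated minus control), the exact binomial
    tail probability of ``k_treat`` successes in ``n_treat`` trials under the
    control rate (upper tail if the treated rate is at least the control
    rate, lower tail otherwise), and the two-sided normal p-value of z.
    Both exact and normal forms are reported because either convention is
    defensible for small strata.
    """
    for k, n, label in ((k_treat, n_treat, "treated"), (k_ctrl, n_ctrl, "control")):
        if n < 0 or not 0 <= k <= n:
            raise ValueError(f"invalid counts for {label}: k={k}, n={n}")
    if n_ctrl == 0:
        raise ValueError("control group is empty")
    if n_treat == 0:
        raise ValueError("treated group is empty")
    p_t = k_treat / n_treat
    p_c = k_ctrl / n_ctrl
    pooled = (k_treat + k_ctrl) / (n_treat + n_ctrl)
    denom = pooled * (1.0 - pooled) * (1.0 / n_treat + 1.0 / n_ctrl)
    z = (p_t - p_c) / np.sqrt(denom) if denom > 0 else 0.0
    if p_t >= p_c:
        p_exact = float(stats.binom.sf(k_treat - 1, n_treat, p_c))
    else:
        p_exact = float(stats.binom.cdf(k_treat, n_treat, p_c))
    p_normal = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p_exact, p_normal
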