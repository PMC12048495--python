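"""Inverse-correlation-weighted variable network.

Pipeline: pairwise Pearson correlation matrix → undirected graph whose edge
weights are 1/|r| (strong associations become short edges, so shortest paths
trace chains of strongly related variables) → node pruning → VIF-scaled node
sizes and period colors → deterministic force-directed layout and export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import EXCLUDED_NODES, MILESTONES, VariableCatalog
from .estimators import VIFTable
from .simulate import Cohort

__all__ = [
    "CorrelationMatrix",
    "VarNetwork",
    "correlation_matrix",
    "build_network",
    "prune_nodes",
    "layout",
    "export_graphml",
    "export_edge_tsv",
    "PERIOD_COLORS",
    "HIGHLIGHT_VIFS",
]

PERIOD_COLORS = {1: "skyblue", 2: "lightgreen", 3: "lightcoral"}

#: Reported VIF values for the five highlighted variables (treatment,
#: testosterone, PFMT frequency, core training, T-cho); used as the default
#: node-size highlight map.
HIGHLIGHT_VIFS = {"aq": 3.023, "ai": 2.778, "an": 1.678, "l": 1.072, "ak": 1.199}

DEFAULT_MIN_ABS_R = 0.05


@dataclass
class CorrelationMatrix:
    codes: list[str]
    r: pd.DataFrame                # symmetric, unit diagonal; NaN where undefined
    n_pairs: pd.DataFrame
    constant: list[str] = field(default_factory=list)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.r.loc[a, b])


@dataclass
class VarNetwork:
    """Weighted undirected graph over variable codes.

    Node attributes: ``period``, ``size``, ``color``.  Edge attributes:
    ``r`` (Pearson correlation) and ``weight`` = 1/|r|.
    """

    graph: nx.Graph
    pruned: list[tuple[str, str]] = field(default_factory=list)  # (code, reason)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return list(self.graph.edges(data=True))

    def copy(self) -> "VarNetwork":
        return VarNetwork(graph=self.graph.copy(), pruned=list(self.pruned))


def correlation_matrix(data: Cohort | pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations over all cohort columns.

    Constant columns get NaN rows/columns (flagged, not raised); fewer than
    3 rows is an error.
    """
    df = data.df if isinstance(data, Cohort) else data
    if len(df) < 3:
        raise ValueError(f"need at least 3 rows to correlate (got {len(df)})")
    if df.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    num = df.astype(float)
    r = num.corr(method="pearson")
    notna = num.notna().astype(int)
    n_pairs = notna.T @ notna
    constant = [c for c in num.columns if num[c].nunique(dropna=True) <= 1]
    # enforce exact symmetry / unit diagonal for non-constant columns
    vals = (r.to_numpy() + r.to_numpy().T) / 2.0
    np.fill_diagonal(vals, 1.0)
    r = pd.DataFrame(vals, index=r.index, columns=r.columns)
    for c in constant:
        r.loc[c, :] = np.nan
        r.loc[:, c] = np.nan
    return CorrelationMatrix(codes=list(num.columns), r=r, n_pairs=n_pairs, constant=constant)


def build_network(
    corr: CorrelationMatrix,
    catalog: VariableCatalog,
    vifs: VIFTable | None = None,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
    highlight: dict[str, float] | None = None,
    base_size: float = 300.0,
) -> VarNetwork:
    """Build the weighted variable graph.

    An edge (i, j) exists iff r_ij is defined and |r_ij| ≥ ``min_abs_r``;
    its weight is 1/|r_ij|.  Highlighted nodes get size
    ``base_size × max(vif, 1)``; every node carries its period color tag.
    ``highlight`` defaults to the five reported VIF values
    (:data:`HIGHLIGHT_VIFS`); pass an explicit mapping (e.g. from
    :func:`suipath.estimators.compute_vif`) to size from fitted VIFs instead.
    """
    unknown = [c for c in corr.codes if c not in catalog]
    if unknown:
        raise ValueError(f"correlation codes not in catalog: {unknown}")
    if highlight is None:
        highlight = dict(HIGHLIGHT_VIFS)
        if vifs is not None:
            table = vifs.table.drop(index="const", errors="ignore")
            highlight = {k: float(v) for k, v in table["vif"].items() if np.isfinite(v)}
    G = nx.Graph()
    for code in corr.codes:
        period = catalog.period_of(code)
        size = base_size * max(highlight[code], 1.0) if code in highlight else base_size
        G.add_node(code, period=period, size=size, color=PERIOD_COLORS[period])
    for h in highlight:
        if h not in corr.codes:
            warnings.warn(f"highlight code {h!r} absent from correlation matrix; skipped", stacklevel=2)
    rmat = corr.r
    for i, a in enumerate(corr.codes):
        for b in corr.codes[i + 1:]:
            rv = rmat.loc[a, b]
            if pd.isna(rv) or abs(rv) < min_abs_r or abs(rv) == 0.0:
                continue
            G.add_edge(a, b, r=float(rv), weight=1.0 / abs(float(rv)))
    return VarNetwork(graph=G)


def prune_nodes(
    net: VarNetwork,
    mode: str = "explicit",
    exclusion_list: list[str] | None = None,
    distance_cutoff: float | None = None,
    milestones: tuple[str, ...] = (MILESTONES[0], MILESTONES[-1]),
) -> VarNetwork:
    """Remove less-relevant nodes from the network.

    ``explicit`` mode removes exactly the listed codes (default: the ten
    standard exclusions, :data:`suipath.catalog.EXCLUDED_NODES`).
    ``threshold`` mode removes isolated nodes and nodes whose weighted
    shortest-path distance to the nearest milestone exceeds
    ``distance_cutoff``.  Milestone nodes themselves may never be pruned.
    Weights of surviving edges are untouched.
    """
    out = net.copy()
    G = out.graph
    if mode == "explicit":
        codes = list(EXCLUDED_NODES) if exclusion_list is None else list(exclusion_list)
        missing = [c for c in codes if c not in G]
        if missing:
            raise ValueError(f"cannot prune absent node(s): {missing}")
        bad = [c for c in codes if c in milestones]
        if bad:
            raise ValueError(f"refusing to prune milestone node(s): {bad}")
        for c in codes:
            G.remove_node(c)
            out.pruned.append((c, "explicit exclusion"))
    elif mode == "threshold":
        if distance_cutoff is None:
            distance_cutoff = float("inf")
        present = [m for m in milestones if m in G]
        dist: dict[str, float] = {}
        for m in present:
            for node, d in nx.single_source_dijkstra_path_length(G, m, weight="weight").items():
                dist[node] = min(dist.get(node, float("inf")), d)
        for node in list(G.nodes):
            if node in milestones:
                continue
            if G.degree(node) == 0:
                G.remove_node(node)
                out.pruned.append((node, "isolated"))
            elif dist.get(node, float("inf")) > distance_cutoff:
                G.remove_node(node)
                out.pruned.append((node, f"distance > {distance_cutoff}"))
    else:
        raise ValueError(f"unknown prune mode {mode!r}")
    return out


def layout(net: VarNetwork, seed: int = 0) -> dict[str, np.ndarray]:
    """Deterministic Fruchterman–Reingold (spring) positions.

    Disconnected components are laid out independently and tiled on a grid,
    so unrelated components never interleave.
    """
    G = net.graph
    if G.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if G.number_of_nodes() == 1:
        return {next(iter(G.nodes)): np.zeros(2)}
    components = sorted(nx.connected_components(G), key=lambda c: sorted(c))
    if len(components) == 1:
        return nx.spring_layout(G, seed=seed, weight="weight")
    pos: dict[str, np.ndarray] = {}
    side = int(np.ceil(np.sqrt(len(components))))
    for k, comp in enumerate(components):
        sub = G.subgraph(comp)
        if sub.number_of_nodes() == 1:
            local = {next(iter(sub.nodes)): np.zeros(2)}
        else:
            local = nx.spring_layout(sub, seed=seed + k, weight="weight")
        pts = {n: np.asarray(xy, dtype=float) for n, xy in local.items()}
        center = np.mean(list(pts.values()), axis=0)
        radius = max((np.linalg.norm(v - center) for v in pts.values()), default=0.0)
        scale = 1.0 / radius if radius > 0 else 1.0
        offset = 5.0 * np.array([k % side, k // side], dtype=float)
        for node, xy in pts.items():
            pos[node] = (xy - center) * scale + offset
    return pos


def export_graphml(net: VarNetwork, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(net.graph, path)
    return path


def export_edge_tsv(net: VarNetwork, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"code_a": a, "code_b": b, "r": d["r"], "weight": d["weight"]}
        for a, b, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["code_a", "code_b", "r", "weight"]).to_csv(path, sep="\t", index=False)
    return path
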