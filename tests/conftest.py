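import numpy as np
import pandas as pd
import pytest

from suipath import CohortSpec, default_catalog, generate_causal_benchmark, generate_cohort


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """Default-condition cohort at a few hundred patients per arm."""
    return generate_cohort(CohortSpec(n_treat=200, n_ctrl=200, seed=3), catalog)


@pytest.fixture(scope="session")
def study_cohort(catalog):
    """The 41 + 41 matched-study-sized cohort."""
    return generate_cohort(CohortSpec(seed=11), catalog)


@pytest.fixture(scope="session")
def benchmark():
    """Structural benchmark with known ATE and observed-only confounding."""
    return generate_causal_benchmark(n=4000, effect=42.154, seed=5, confounding=0.8)


def make_random_graph(rng, n_nodes=8, p_edge=0.5):
    """Random weighted graph for path-oracle tests (labels 'a', 'b', ...)."""
    import networkx as nx

    labels = [chr(ord("a") + i) for i in range(n_nodes)]
    G = nx.Graph()
    G.add_nodes_from(labels)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.uniform() < p_edge:
                G.add_edge(labels[i], labels[j], weight=float(rng.uniform(0.2, 5.0)))
    return G


def brute_force_shortest(G, source, target, must_contain=None):
    """Exhaustive simple-path enumeration oracle (≤ 8 nodes)."""
    import networkx as nx

    best = None
    for path in nx.all_simple_paths(G, source, target):
        if must_contain is not None and must_contain not in path:
            continue
        w = sum(G[a][b]["weight"] for a, b in zip(path, path[1:]))
        key = (w, tuple(path))
        if best is None or key < best:
            best = key
    return best  # (weight, nodes) or None
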