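import itertools

import numpy as np
import pytest

from grangernet.panel import PanelDataset


def brute_force_betweenness(adj: np.ndarray) -> np.ndarray:
    """Directed betweenness by exhaustive shortest-path enumeration.

    Independent oracle: BFS distances, explicit enumeration of every
    shortest s->t path, fraction through each node, normalized by
    (n-1)(n-2).
    """
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier, d = [s], 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and dist[s, v] == np.inf and v != s:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt

    def all_shortest_paths(s, t):
        if not np.isfinite(dist[s, t]):
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(tuple(path))
                return
            for v in range(n):
                if adj[u, v] and dist[s, v] == len(path) and \
                        dist[s, v] + dist[v, t] == dist[s, t]:
                    extend(path + [v])
        extend([s])
        return paths

    btw = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for v in range(n):
            if v not in (s, t):
                btw[v] += sum(v in p for p in paths) / len(paths)
    return btw / ((n - 1) * (n - 2))


@pytest.fixture
def small_panel() -> PanelDataset:
    """Deterministic 3-subject x 9-time x 2-variable panel."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(3, 9, 2))
    return PanelDataset(("A", "B", "C"), ("x", "y"), values, condition="regular")


@pytest.fixture
def study_shaped_panel() -> PanelDataset:
    """Panel with the reference study's shape: 6 subjects x 9 times x 8 variables."""
    rng = np.random.default_rng(7)
    names = tuple(f"v{j}" for j in range(8))
    values = rng.normal(size=(6, 9, 8))
    return PanelDataset(tuple(f"S{i}" for i in range(6)), names, values)
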