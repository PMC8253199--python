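"""Weighted causal adjacency construction and directed-graph metrics.

The inference pipeline summarizes V(V-1) pairwise causality tests as a
directed graph: an edge cause -> effect is present when the pair's test is
significant at the chosen level, and carries a positive strength (Wald
statistic by default — larger means stronger evidence of Granger
causality; zero means no edge).  Centralities and density are computed on
the *binary* thresholded graph: in/out-degree centrality is the in/out
edge count divided by n-1, betweenness is directed unweighted
shortest-path betweenness normalized by (n-1)(n-2), and density is the
edge count divided by the n(n-1) possible directed edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "CausalNetwork",
    "CentralityReport",
    "build_adjacency",
    "degree_centralities",
    "betweenness_centrality",
    "density",
    "realize_degree_sequence",
    "centrality_report",
    "hub_report",
    "export_graph",
    "read_edgelist",
    "round2",
]

WEIGHT_MODES = ("wald", "one_minus_p", "coef")


def round2(x: float) -> float:
    """Round to 2 decimals, half away from zero (report-layer convention)."""
    return math.floor(abs(x) * 100.0 + 0.5) / 100.0 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CausalNetwork:
    """Directed weighted adjacency over named nodes.

    ``weights[j, k]`` is the strength of the edge node_j -> node_k; 0 means
    no edge; the diagonal is identically zero (no self-loops).
    """

    nodes: tuple[str, ...]
    weights: np.ndarray
    alpha: float = 0.05
    weight_mode: str = "wald"

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        w = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed (nonzero diagonal)")
        if np.any(w < 0):
            raise ValueError("edge weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    def edges(self) -> list[tuple[str, str, float]]:
        """(cause, effect, weight) triples in row-major node order."""
        return [
            (self.nodes[j], self.nodes[k], float(self.weights[j, k]))
            for j in range(self.n)
            for k in range(self.n)
            if self.weights[j, k] > 0
        ]

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges())
        return g

    def binary(self) -> np.ndarray:
        return (self.weights > 0).astype(int)


def build_adjacency(results, alpha: float = 0.05,
                    weight_mode: str = "wald",
                    nodes: tuple[str, ...] | None = None,
                    warn=None) -> CausalNetwork:
    """Threshold pairwise test results into a weighted adjacency matrix.

    Parameters
    ----------
    results
        Iterable of :class:`~grangernet.granger.GrangerPairResult` covering
        distinct ordered (cause, effect) pairs over a common variable set.
    alpha
        Per-pair significance level; an edge is present iff p_value < alpha.
    weight_mode
        Strength of a significant edge: ``"wald"`` (the Wald statistic,
        default), ``"one_minus_p"`` (1 - p), or ``"coef"`` (|first
        bias-corrected cross-lag coefficient|).
    nodes
        Optional explicit node order; inferred from the results otherwise.
    warn
        Optional callable invoked with a message for each missing pair
        (treated as an absent edge).
    """
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight_mode {weight_mode!r}; use one of {WEIGHT_MODES}")
    results = list(results)
    if nodes is None:
        seen: dict[str, None] = {}
        for r in results:
            seen.setdefault(r.cause)
            seen.setdefault(r.effect)
        nodes = tuple(seen)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n))
    covered = set()
    for r in results:
        pair = (r.cause, r.effect)
        if pair in covered:
            raise ValueError(f"duplicate pair {pair[0]} -> {pair[1]}")
        covered.add(pair)
        if r.p_value < alpha:
            if weight_mode == "wald":
                w[index[r.cause], index[r.effect]] = r.wald
            elif weight_mode == "one_minus_p":
                w[index[r.cause], index[r.effect]] = 1.0 - r.p_value
            else:
                w[index[r.cause], index[r.effect]] = abs(r.theta_hpj[r.lag_order])
    missing = [
        (c, e) for c in nodes for e in nodes
        if c != e and (c, e) not in covered
    ]
    if missing and warn is not None:
        for c, e in missing:
            warn(f"no test result for pair {c} -> {e}; treated as absent edge")
    return CausalNetwork(nodes=nodes, weights=w, alpha=alpha, weight_mode=weight_mode)


# -- metrics --------------------------------------------------------------

def degree_centralities(net: CausalNetwork) -> dict[str, tuple[float, float]]:
    """Per-node (indegree_centrality, outdegree_centrality).

    Each is the incoming (resp. outgoing) edge count divided by n-1, the
    number of possible counterpart nodes; full precision (report layers
    round to 2 decimals).
    """
    if net.n < 2:
        raise ValueError("degree centralities need at least 2 nodes")
    b = net.binary()
    indeg = b.sum(axis=0) / (net.n - 1)
    outdeg = b.sum(axis=1) / (net.n - 1)
    return {v: (float(indeg[i]), float(outdeg[i])) for i, v in enumerate(net.nodes)}


def betweenness_centrality(net: CausalNetwork, normalized: bool = True) -> dict[str, float]:
    """Directed unweighted shortest-path betweenness per node.

    For node v: sum over ordered pairs (s, t), s != t != v, of the fraction
    of shortest directed s->t paths passing through v (unreachable pairs
    contribute 0), normalized by (n-1)(n-2) when ``normalized``.
    Edge presence only — weights play no role in path length.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((c, e) for c, e, _ in net.edges())
    return {v: float(b) for v, b in
            nx.betweenness_centrality(g, normalized=normalized).items()}


def density(net: CausalNetwork) -> float:
    """Directed graph density: edge count / (n(n-1))."""
    if net.n < 2:
        raise ValueError("density needs at least 2 nodes")
    return net.n_edges / (net.n * (net.n - 1))


def realize_degree_sequence(out_counts, in_counts,
                            nodes: tuple[str, ...] | None = None) -> CausalNetwork:
    """Construct a simple digraph with the exact requested degree sequence.

    Solves the bipartite b-matching by max-flow: a source feeds each node's
    out-stub capacity, each node's in-stub capacity drains to a sink, and
    unit-capacity arcs connect distinct node pairs (no self-loops, no
    multi-edges).  Deterministic given the input order.  Returns a
    binary-weight :class:`CausalNetwork`.

    Raises
    ------
    ValueError
        If the sums differ, a count exceeds n-1, or no simple digraph has
        the requested sequence (max-flow short of the stub total).
    """
    out_counts = [int(c) for c in out_counts]
    in_counts = [int(c) for c in in_counts]
    n = len(out_counts)
    if len(in_counts) != n:
        raise ValueError("out_counts and in_counts must have the same length")
    if sum(out_counts) != sum(in_counts):
        raise ValueError(
            f"infeasible degree sequence: sum(out)={sum(out_counts)} != "
            f"sum(in)={sum(in_counts)}"
        )
    for name, counts in (("out", out_counts), ("in", in_counts)):
        bad = [i for i, c in enumerate(counts) if not 0 <= c <= n - 1]
        if bad:
            raise ValueError(
                f"infeasible degree sequence: {name}-degree at positions {bad} "
                f"outside [0, n-1={n - 1}]"
            )
    if nodes is None:
        nodes = tuple(f"v{i}" for i in range(n))
    nodes = tuple(nodes)

    g = nx.DiGraph()
    for i in range(n):
        g.add_edge("src", ("o", i), capacity=out_counts[i])
        g.add_edge(("i", i), "snk", capacity=in_counts[i])
        for j in range(n):
            if i != j:
                g.add_edge(("o", i), ("i", j), capacity=1)
    flow_value, flow = nx.maximum_flow(
        g, "src", "snk", flow_func=nx.algorithms.flow.edmonds_karp
    )
    total = sum(out_counts)
    if flow_value != total:
        raise ValueError(
            f"infeasible degree sequence: only {flow_value} of {total} edge "
            "stubs can be matched in a simple digraph (Gale-Ryser violation)"
        )
    w = np.zeros((n, n))
    for i in range(n):
        for j, f in flow[("o", i)].items():
            if j != "snk" and f > 0:
                w[i, j[1]] = 1.0
    return CausalNetwork(nodes=nodes, weights=w, alpha=1.0, weight_mode="coef")


# -- reporting ------------------------------------------------------------

@dataclass(frozen=True)
class CentralityReport:
    """Per-node centralities plus whole-graph summaries for one network."""

    nodes: tuple[str, ...]
    betweenness: dict[str, float]
    indegree_centrality: dict[str, float]
    outdegree_centrality: dict[str, float]
    density: float
    n_edges: int

    def ranking(self, metric: str) -> list[tuple[float, list[str]]]:
        """Nodes grouped by metric value, best first; ties reported jointly."""
        vals = getattr(self, metric)
        groups: dict[float, list[str]] = {}
        for v in self.nodes:
            groups.setdefault(round(vals[v], 12), []).append(v)
        return sorted(groups.items(), key=lambda kv: -kv[0])


def centrality_report(net: CausalNetwork) -> CentralityReport:
    """Compute the full centrality/density report for a network."""
    deg = degree_centralities(net)
    return CentralityReport(
        nodes=net.nodes,
        betweenness=betweenness_centrality(net),
        indegree_centrality={v: d[0] for v, d in deg.items()},
        outdegree_centrality={v: d[1] for v, d in deg.items()},
        density=density(net),
        n_edges=net.n_edges,
    )


def hub_report(report: CentralityReport) -> dict[str, dict]:
    """Top node(s) per metric; exact ties are reported jointly."""
    out = {}
    for metric in ("betweenness", "indegree_centrality", "outdegree_centrality"):
        (value, names), *_ = report.ranking(metric)
        out[metric] = {"nodes": names, "value": value,
                       "tie": len(names) > 1}
    return out


# -- export ---------------------------------------------------------------

def export_graph(net: CausalNetwork, path: str, fmt: str = "edgelist-tsv") -> None:
    """Write the network as ``edgelist-tsv``, ``graphml``, or ``dot``.

    The edge-list TSV (columns cause, effect, weight, full precision)
    round-trips exactly through :func:`read_edgelist`.
    """
    if fmt == "edgelist-tsv":
        with open(path, "w") as fh:
            fh.write("cause\teffect\tweight\n")
            for c, e, w in net.edges():
                fh.write(f"{c}\t{e}\t{w!r}\n")
    elif fmt == "graphml":
        g = net.to_digraph()
        nx.write_graphml(g, path)
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph causal {\n")
            for v in net.nodes:
                fh.write(f'  "{v}";\n')
            for c, e, w in net.edges():
                fh.write(f'  "{c}" -> "{e}" [weight={w!r}, label="{round2(w)}"];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_edgelist(path: str, nodes: tuple[str, ...] | None = None,
                  alpha: float = 0.05, weight_mode: str = "wald") -> CausalNetwork:
    """Read an edge-list TSV written by :func:`export_graph` back into a network."""
    edges = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["cause", "effect", "weight"]:
            raise ValueError(f"unexpected edge-list header {header}")
        for line in fh:
            c, e, w = line.rstrip("\n").split("\t")
            edges.append((c, e, float(w)))
    if nodes is None:
        seen: dict[str, None] = {}
        for c, e, _ in edges:
            seen.setdefault(c)
            seen.setdefault(e)
        nodes = tuple(seen)
    index = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for c, e, weight in edges:
        w[index[c], index[e]] = weight
    return CausalNetwork(nodes=nodes, weights=w, alpha=alpha, weight_mode=weight_mode)
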