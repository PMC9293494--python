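"""Shared test utilities: random-graph generation and independent oracles.

Everything here is deliberately independent of the package's own
algorithms: oracles use networkx, dense linear algebra, exact rational
arithmetic, or naive exhaustive enumeration.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np

from herbnetpharm.graph import InteractionGraph


def random_graph(rng: np.random.Generator, n_max: int = 8, p: float = 0.4,
                 require_edge: bool = True, connected: bool = False) -> InteractionGraph:
    """Erdos-Renyi-style random simple graph with string node ids."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        nodes = [f"n{i}" for i in range(n)]
        g = InteractionGraph(nodes=nodes)
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
        if require_edge and g.n_edges == 0:
            continue
        if connected and not nx.is_connected(to_networkx(g)):
            continue
        return g


def to_networkx(g: InteractionGraph) -> nx.Graph:
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(g.edges())
    return h


def from_networkx(h: nx.Graph) -> InteractionGraph:
    g = InteractionGraph(nodes=[str(n) for n in h.nodes])
    for u, v in h.edges:
        if u != v:
            g.add_edge(str(u), str(v))
    return g


# ---------------------------------------------------------------------------
# centrality oracles
# ---------------------------------------------------------------------------


def closeness_oracle(g: InteractionGraph) -> dict[str, float]:
    """Component-restricted closeness via dense Floyd-Warshall."""
    nodes = g.nodes
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges():
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    out = {}
    for v in nodes:
        row = dist[idx[v]]
        reach = row[np.isfinite(row)]
        out[v] = (len(reach) - 1) / reach.sum() if reach.sum() > 0 else 0.0
    return out


def betweenness_oracle(g: InteractionGraph) -> dict[str, float]:
    """Unnormalized betweenness by exhaustive simple-path enumeration."""
    h = to_networkx(g)
    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        if not nx.has_path(h, s, t):
            continue
        paths = list(nx.all_simple_paths(h, s, t))
        dmin = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == dmin]
        for v in g.nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / len(shortest)
    return bc


def eigenvector_oracle(g: InteractionGraph) -> dict[str, float]:
    """Principal eigenvector via dense symmetric eigendecomposition."""
    nodes = g.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v in g.edges():
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    w, vecs = np.linalg.eigh(a)
    lead = np.abs(vecs[:, np.argmax(w)])
    lead /= np.linalg.norm(lead)
    return {v: float(lead[idx[v]]) for v in nodes}


def lac_oracle(g: InteractionGraph) -> dict[str, float]:
    h = to_networkx(g)
    out = {}
    for v in g.nodes:
        nbrs = list(h[v])
        if not nbrs:
            out[v] = 0.0
        else:
            sub = h.subgraph(nbrs)
            out[v] = 2.0 * sub.number_of_edges() / len(nbrs)
    return out


def nc_oracle(g: InteractionGraph) -> dict[str, float]:
    h = to_networkx(g)
    out = {}
    for v in g.nodes:
        total = 0.0
        for u in h[v]:
            denom = min(h.degree(u), h.degree(v)) - 1
            if denom > 0:
                total += len(list(nx.common_neighbors(h, u, v))) / denom
        out[v] = total
    return out


def key_node_rule_oracle(g: InteractionGraph, strict: bool = True) -> set[str]:
    """Independent re-implementation of the above-mean AND rule using the
    oracle metrics (networkx degree/betweenness plus the oracles above)."""
    h = to_networkx(g)
    metrics = {
        "dc": dict(h.degree()),
        "cc": closeness_oracle(g),
        "bc": nx.betweenness_centrality(h, normalized=False),
        "ec": eigenvector_oracle(g),
        "lac": lac_oracle(g),
        "nc": nc_oracle(g),
    }
    key = set(g.nodes)
    for vals in metrics.values():
        mean = sum(vals.values()) / len(vals)
        if strict:
            key &= {v for v in g.nodes if vals[v] > mean}
        else:
            key &= {v for v in g.nodes if vals[v] >= mean}
    return key


# ---------------------------------------------------------------------------
# enrichment oracle
# ---------------------------------------------------------------------------


def hypergeom_tail_exact(k: int, n: int, K: int, M: int) -> Fraction:
    """Upper tail as an exact rational via big-integer binomials."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(M - K, n - i), comb(M, n))
    return total


def bh_oracle(pvals: list[float]) -> list[float]:
    """Step-up BH by the textbook formula, returned in input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
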