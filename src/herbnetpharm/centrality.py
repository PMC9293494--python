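"""Six-metric topological screening of network nodes.

The screen follows the CytoNCA convention family: degree (DC), closeness
(CC), betweenness (BC, unnormalized, each unordered pair counted once),
eigenvector (EC, L2-normalized principal eigenvector), local average
connectivity (LAC) and network centrality (NC, the sum of edge clustering
coefficients over incident edges). A node is a *key target* when it
exceeds the network-wide mean on all six metrics simultaneously; the
*central network* is the subgraph induced on the key targets.

Because the screen only compares each metric to its own mean, it is
invariant to any per-metric rescaling; normalization choices are
reporting conventions, not screening choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceWarning, ValidationError
from .graph import InteractionGraph

__all__ = [
    "METRICS",
    "CentralityTable",
    "ScreeningResult",
    "degree_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "eigenvector_centrality",
    "local_average_connectivity",
    "network_centrality",
    "centrality_table",
    "screen_key_nodes",
]

METRICS = ("dc", "cc", "bc", "ec", "lac", "nc")


def degree_centrality(g: InteractionGraph) -> dict[str, float]:
    """DC: number of incident edges."""
    return {v: float(g.degree(v)) for v in g.nodes}


def _bfs_distances(g: InteractionGraph, source: str) -> dict[str, int]:
    dist = {source: 0}
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = d
                    nxt.append(w)
        frontier = nxt
    return dist


def closeness_centrality(g: InteractionGraph) -> dict[str, float]:
    """CC restricted to each node's connected component.

    cc(v) = (|C_v| - 1) / sum of BFS distances from v within its component;
    isolated nodes get 0. On a connected graph this is the classical
    closeness; on a disconnected one it never mixes components.
    """
    out: dict[str, float] = {}
    for v in g.nodes:
        dist = _bfs_distances(g, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def betweenness_centrality(g: InteractionGraph) -> dict[str, float]:
    """BC by Brandes' single-source accumulation, unnormalized.

    Each unordered source-target pair contributes once:
    bc(v) = sum over {s,t}, s != v != t, of sigma_st(v) / sigma_st.
    """
    bc = {v: 0.0 for v in g.nodes}
    for s in g.nodes:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in g.nodes}
        sigma = {v: 0.0 for v in g.nodes}
        sigma[s] = 1.0
        dist = {s: 0}
        queue = [s]
        qi = 0
        while qi < len(queue):
            u = queue[qi]
            qi += 1
            stack.append(u)
            for w in g.neighbors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    pred[w].append(u)
        delta = {v: 0.0 for v in g.nodes}
        while stack:
            w = stack.pop()
            for u in pred[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints
    return {v: b / 2.0 for v, b in bc.items()}


def eigenvector_centrality(
    g: InteractionGraph, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[str, float]:
    """EC: principal adjacency eigenvector by power iteration.

    Iterates the shifted operator A + I (same eigenvectors as A, but
    primitive on connected graphs, so the iteration cannot oscillate on
    bipartite structures), starting from the uniform vector and
    L2-normalizing every step; stops when successive iterates differ by
    less than ``tol`` in max-norm. Non-convergence raises
    :class:`ConvergenceWarning` (flagged, not silent) and returns the
    last iterate.
    """
    if g.n_edges == 0:
        raise ValidationError("eigenvector centrality needs at least one edge")
    nodes = g.nodes
    index = {v: i for i, v in enumerate(nodes)}
    nbrs = [np.fromiter((index[w] for w in g.neighbors(v)), dtype=np.intp) for v in nodes]
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = np.array([x[nb].sum() for nb in nbrs]) + x
        norm = np.linalg.norm(y)
        if norm == 0:  # pragma: no cover - only if all mass on isolates
            break
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        warnings.warn(
            f"power iteration did not converge in {max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    x = np.abs(x)
    return {v: float(x[index[v]]) for v in nodes}


def local_average_connectivity(g: InteractionGraph) -> dict[str, float]:
    """LAC: average within-neighbourhood degree of a node's neighbours.

    lac(v) = 2 * e(N(v)) / |N(v)| where e(N(v)) counts edges among v's
    neighbours; 0 for isolated nodes.
    """
    out: dict[str, float] = {}
    for v in g.nodes:
        nbrs = g.neighbors(v)
        if not nbrs:
            out[v] = 0.0
            continue
        e = sum(1 for u in nbrs for w in g.neighbors(u) if w in nbrs) // 2
        out[v] = 2.0 * e / len(nbrs)
    return out


def edge_clustering_coefficient(g: InteractionGraph, u: str, v: str) -> float:
    """ECC(u,v) = |common neighbours| / min(deg u - 1, deg v - 1); 0 when the
    denominator vanishes (an endpoint of degree 1)."""
    denom = min(g.degree(u), g.degree(v)) - 1
    if denom <= 0:
        return 0.0
    z = len(g.neighbors(u) & g.neighbors(v))
    return z / denom


def network_centrality(g: InteractionGraph) -> dict[str, float]:
    """NC: sum of edge clustering coefficients over incident edges."""
    out: dict[str, float] = {}
    for v in g.nodes:
        out[v] = sum(edge_clustering_coefficient(g, v, u) for u in g.neighbors(v))
    return out


@dataclass
class CentralityTable:
    """Per-node values of the six metrics plus their network-wide means."""

    values: pd.DataFrame  # index: node id; columns: METRICS
    means: pd.Series  # index: METRICS
    ec_converged: bool = True

    @property
    def nodes(self) -> list[str]:
        return list(self.values.index)


def centrality_table(g: InteractionGraph) -> CentralityTable:
    """Compute all six metrics on one graph and attach per-metric means."""
    if g.n_edges == 0:
        raise ValidationError("centrality table needs a graph with >= 1 edge")
    ec_converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        cols = {
            "dc": degree_centrality(g),
            "cc": closeness_centrality(g),
            "bc": betweenness_centrality(g),
            "ec": eigenvector_centrality(g),
            "lac": local_average_connectivity(g),
            "nc": network_centrality(g),
        }
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            ec_converged = False
    frame = pd.DataFrame(cols, index=pd.Index(g.nodes, name="node"), columns=list(METRICS))
    return CentralityTable(values=frame, means=frame.mean(axis=0), ec_converged=ec_converged)


@dataclass
class ScreeningResult:
    """Outcome of the above-mean key-target screen."""

    key_nodes: list[str]  # sorted by DC descending, ties by id
    passes: pd.DataFrame  # boolean, node x metric
    central: InteractionGraph  # induced on key_nodes


def screen_key_nodes(
    table: CentralityTable, g: InteractionGraph, strict: bool = True
) -> ScreeningResult:
    """Select nodes above the mean on ALL six metrics (the AND rule).

    ``strict`` compares with ``>`` (the literal reading of the rule);
    ``strict=False`` uses ``>=``. An empty key set is a legal outcome —
    on a vertex-transitive graph nothing strictly exceeds any mean.
    """
    vals, means = table.values, table.means
    passes = vals.gt(means, axis=1) if strict else vals.ge(means, axis=1)
    key = passes.all(axis=1)
    key_nodes = sorted(
        vals.index[key], key=lambda n: (-vals.at[n, "dc"], n)
    )
    return ScreeningResult(
        key_nodes=key_nodes, passes=passes, central=g.subgraph(key_nodes)
    )
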