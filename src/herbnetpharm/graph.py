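"""Undirected simple graph over string node identifiers.

This is the shared container for every network the pipeline touches: the
compound-target bipartite network (nodes are compounds and gene symbols),
protein-protein interaction (PPI) subnetworks, and the merged anticataract
network. It deliberately stays minimal — undirected, unweighted, no
self-loops, no parallel edges — because nothing downstream (centrality
screening, dense-module detection) uses directions or weights.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping

from .errors import ValidationError

__all__ = ["InteractionGraph"]


class InteractionGraph:
    """An undirected simple graph with insertion-ordered string nodes.

    Parameters
    ----------
    nodes :
        Initial node identifiers.
    edges :
        Iterable of ``(u, v)`` pairs; endpoints are added as nodes.
        Self-loops raise :class:`ValidationError`; duplicates (in either
        orientation) are collapsed silently.
    node_kind :
        Optional map ``id -> kind`` (e.g. ``"compound"`` / ``"gene"``) used
        by bipartite networks.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
        node_kind: Mapping[str, str] | None = None,
    ):
        self._adj: dict[str, set[str]] = {}
        self._n_edges = 0
        self.node_kind: dict[str, str] = dict(node_kind) if node_kind else {}
        for n in nodes:
            self.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -----------------------------------------------------

    def add_node(self, n: str) -> None:
        if not isinstance(n, str) or not n:
            raise ValidationError(f"node id must be a non-empty string, got {n!r}")
        self._adj.setdefault(n, set())

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValidationError(f"self-loop on {u!r} is not allowed")
        self.add_node(u)
        self.add_node(v)
        if v not in self._adj[u]:
            self._adj[u].add(v)
            self._adj[v].add(u)
            self._n_edges += 1

    def remove_node(self, n: str) -> None:
        for nbr in self._adj.pop(n):
            self._adj[nbr].discard(n)
            self._n_edges -= 1
        self.node_kind.pop(n, None)

    # -- inspection -------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Nodes in insertion order."""
        return list(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    def edges(self) -> Iterator[tuple[str, str]]:
        """Each undirected edge once, as a lexicographically sorted pair."""
        seen: set[str] = set()
        for u in self._adj:
            for v in self._adj[u]:
                if v not in seen:
                    yield (u, v) if u < v else (v, u)
            seen.add(u)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges())

    def has_node(self, n: str) -> bool:
        return n in self._adj

    def has_edge(self, u: str, v: str) -> bool:
        return u in self._adj and v in self._adj[u]

    def neighbors(self, n: str) -> set[str]:
        return set(self._adj[n])

    def degree(self, n: str) -> int:
        return len(self._adj[n])

    def isolated_nodes(self) -> list[str]:
        return [n for n, nbrs in self._adj.items() if not nbrs]

    # -- derived graphs ---------------------------------------------------

    def subgraph(self, nodes: Iterable[str]) -> "InteractionGraph":
        """Induced subgraph on ``nodes`` (unknown ids ignored), kinds kept."""
        keep = [n for n in self._adj if n in set(nodes)]
        kept = set(keep)
        g = InteractionGraph(nodes=keep)
        for u in keep:
            for v in self._adj[u]:
                if v in kept and u < v:
                    g.add_edge(u, v)
        g.node_kind = {n: k for n, k in self.node_kind.items() if n in kept}
        return g

    def copy(self) -> "InteractionGraph":
        g = InteractionGraph(nodes=self.nodes, node_kind=self.node_kind)
        for u, v in self.edges():
            g.add_edge(u, v)
        return g

    def same_structure(self, other: "InteractionGraph") -> bool:
        """Equality on node and edge sets (kinds and order ignored)."""
        return set(self._adj) == set(other._adj) and self.edge_set() == other.edge_set()

    def __contains__(self, n: str) -> bool:
        return n in self._adj

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionGraph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
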