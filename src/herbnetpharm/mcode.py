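"""MCODE-style dense-module detection.

Implements the classic molecular-complex-detection scheme: each node is
weighted by the density of the highest k-core of its closed neighbourhood
times that core's k; modules grow greedily from the highest-weighted
unassigned seed, admitting neighbours whose weight is within a
vertex-weight percentage (vwp) of the seed's; an optional haircut prunes
singly-connected members. A module's score is its density times its node
count — a 6-node module with every edge but one present scores
(14/15) * 6 = 5.60.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .graph import InteractionGraph

__all__ = [
    "McodeParams",
    "ModuleResult",
    "mcode_weight_nodes",
    "mcode_find_modules",
    "module_score",
]


@dataclass(frozen=True)
class McodeParams:
    """Published tool defaults: vwp 0.2, haircut on, fluff off, min size 3."""

    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    min_size: int = 3

    def __post_init__(self):
        if not 0 <= self.vwp < 1:
            raise ValidationError(f"vwp must be in [0, 1), got {self.vwp}")
        if self.min_size < 2:
            raise ValidationError(f"min_size must be >= 2, got {self.min_size}")


@dataclass(frozen=True)
class ModuleResult:
    """A detected module: node set, induced edge count, density, score."""

    nodes: frozenset[str]
    n_edges: int
    density: float
    score: float
    seed: str

    @property
    def n(self) -> int:
        return len(self.nodes)


def _density(n_nodes: int, n_edges: int) -> float:
    """Simple-graph density 2E / (n(n-1)); 0 for fewer than two nodes."""
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def _core_decomposition(g: InteractionGraph) -> dict[str, int]:
    """Core number of every node by iterative minimum-degree peeling."""
    deg = {v: g.degree(v) for v in g.nodes}
    core: dict[str, int] = {}
    remaining = set(g.nodes)
    k = 0
    while remaining:
        v = min(remaining, key=lambda x: (deg[x], x))
        k = max(k, deg[v])
        core[v] = k
        remaining.discard(v)
        for u in g.neighbors(v):
            if u in remaining:
                deg[u] -= 1
    return core


def _highest_kcore(g: InteractionGraph) -> tuple[int, InteractionGraph]:
    """The maximum-k core subgraph and its k; (0, empty) for edgeless input."""
    if g.n_edges == 0:
        return 0, InteractionGraph()
    core = _core_decomposition(g)
    kmax = max(core.values())
    return kmax, g.subgraph([v for v, c in core.items() if c >= kmax])


def mcode_weight_nodes(g: InteractionGraph) -> dict[str, float]:
    """Core-clustering weight: k * density of the highest k-core of N[v]."""
    weights: dict[str, float] = {}
    for v in g.nodes:
        closed = g.subgraph(g.neighbors(v) | {v})
        kmax, core = _highest_kcore(closed)
        weights[v] = kmax * _density(core.n_nodes, core.n_edges)
    return weights


def module_score(g: InteractionGraph, nodes: set[str], seed: str | None = None) -> ModuleResult:
    """Score a node set as a module: density x size on the induced subgraph."""
    nodes = set(nodes)
    if len(nodes) < 2:
        raise ValidationError("a module needs at least 2 nodes")
    unknown = nodes - set(g.nodes)
    if unknown:
        raise ValidationError(f"nodes not in graph: {sorted(unknown)}")
    sub = g.subgraph(nodes)
    density = _density(sub.n_nodes, sub.n_edges)
    return ModuleResult(
        nodes=frozenset(nodes),
        n_edges=sub.n_edges,
        density=density,
        score=density * len(nodes),
        seed=seed if seed is not None else min(nodes),
    )


def _expand(g: InteractionGraph, seed: str, weights: dict[str, float],
            assigned: set[str], threshold: float) -> set[str]:
    """Breadth-first module growth from a seed."""
    module = {seed}
    queue = [seed]
    while queue:
        u = queue.pop(0)
        for v in sorted(g.neighbors(u)):
            if v in module or v in assigned:
                continue
            if weights[v] >= threshold:
                module.add(v)
                queue.append(v)
    return module


def _haircut(g: InteractionGraph, module: set[str]) -> set[str]:
    """Iteratively drop members with fewer than 2 connections in the module."""
    module = set(module)
    changed = True
    while changed and len(module) > 1:
        changed = False
        sub = g.subgraph(module)
        for v in sorted(module):
            if sub.degree(v) < 2:
                module.discard(v)
                changed = True
                break
    return module


def mcode_find_modules(
    g: InteractionGraph, params: McodeParams | None = None
) -> list[ModuleResult]:
    """Detect dense modules.

    Seeds are taken in decreasing weight (ties by node id); each node
    joins at most one module. A neighbour is admitted when its weight is
    at least ``(1 - vwp)`` times the seed's weight. Modules smaller than
    ``min_size`` after post-processing are discarded (their nodes stay
    consumed, as in the original tool). Results are sorted by score
    descending, ties by size descending then seed id.
    """
    p = params or McodeParams()
    weights = mcode_weight_nodes(g)
    assigned: set[str] = set()
    results: list[ModuleResult] = []
    for seed in sorted(g.nodes, key=lambda v: (-weights[v], v)):
        if seed in assigned or weights[seed] <= 0:
            continue
        module = _expand(g, seed, weights, assigned, (1.0 - p.vwp) * weights[seed])
        assigned |= module
        if p.haircut:
            module = _haircut(g, module)
        if p.fluff:
            fringe = set()
            for v in sorted(module):
                for u in sorted(g.neighbors(v)):
                    if u in module or u in assigned or u in fringe:
                        continue
                    closed = g.subgraph(g.neighbors(u) | {u})
                    if _density(closed.n_nodes, closed.n_edges) > p.fluff_density:
                        fringe.add(u)
            module |= fringe
            assigned |= fringe
        if len(module) >= max(p.min_size, 2):
            results.append(module_score(g, module, seed=seed))
    results.sort(key=lambda m: (-m.score, -m.n, m.seed))
    return results
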