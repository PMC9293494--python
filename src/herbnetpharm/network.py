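"""Network assembly: compound-target bipartite net, PPI subnetworks, merge.

The background interactome is a user-supplied undirected edge list over
gene symbols. Disease and compound PPI subnetworks are induced on seed
gene sets without neighbour expansion; the merged anticataract network is
the induced subgraph on the union of the two seed sets, with per-node
provenance (compound / disease / shared).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .graph import InteractionGraph
from .io import CompoundRecord, TargetAssociation

__all__ = [
    "CompoundTargetBuild",
    "InducedSubgraph",
    "MergedNetwork",
    "build_compound_target_network",
    "degree_ranking",
    "induced_ppi_subgraph",
    "merge_target_networks",
    "shared_targets",
]


@dataclass
class CompoundTargetBuild:
    graph: InteractionGraph
    n_dropped_associations: int
    """Associations whose mol_id is not an active compound."""


def build_compound_target_network(
    active: list[CompoundRecord], assoc: list[TargetAssociation]
) -> CompoundTargetBuild:
    """Build the bipartite compound-target network.

    Nodes are the active compounds that have at least one association,
    plus their target genes; edges are the distinct (compound, gene)
    pairs. Active compounds with no target data are excluded from the node
    set (they would be isolated). A gene symbol colliding with a compound
    id is rejected — the two kinds share one node namespace.
    """
    active_ids = {r.mol_id for r in active}
    g = InteractionGraph()
    dropped = 0
    for a in assoc:
        if a.mol_id not in active_ids:
            dropped += 1
            continue
        if a.gene in active_ids:
            raise ValidationError(
                f"gene symbol {a.gene!r} collides with a compound id"
            )
        g.add_edge(a.mol_id, a.gene)
        g.node_kind[a.mol_id] = "compound"
        g.node_kind[a.gene] = "gene"
    return CompoundTargetBuild(graph=g, n_dropped_associations=dropped)


def degree_ranking(g: InteractionGraph, kind: str) -> pd.DataFrame:
    """Rank nodes of one kind by degree (descending, ties by id).

    ``kind`` is ``"compound"`` or ``"gene"``; requires ``node_kind`` set.
    """
    if kind not in ("compound", "gene"):
        raise ConfigurationError(f"unknown node kind {kind!r}")
    rows = [
        (n, g.degree(n)) for n in g.nodes if g.node_kind.get(n) == kind
    ]
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.DataFrame(rows, columns=["id", "degree"])


@dataclass
class InducedSubgraph:
    graph: InteractionGraph
    missing_seeds: set[str]
    """Seeds absent from the background interactome."""
    n_isolated_dropped: int = 0


def induced_ppi_subgraph(
    background: InteractionGraph, seeds: set[str], drop_isolated: bool = True
) -> InducedSubgraph:
    """Induce the PPI subnetwork of a seed gene set.

    Keeps exactly the background edges with both endpoints in ``seeds``
    (no neighbour expansion). With ``drop_isolated``, nodes left without
    any connection are removed, mirroring the usual PPI-network
    convention of discarding unconnected proteins.
    """
    if not seeds:
        raise ValidationError("seed set is empty")
    missing = {s for s in seeds if not background.has_node(s)}
    sub = background.subgraph(seeds)
    n_dropped = 0
    if drop_isolated:
        for n in sub.isolated_nodes():
            sub.remove_node(n)
            n_dropped += 1
    return InducedSubgraph(graph=sub, missing_seeds=missing, n_isolated_dropped=n_dropped)


@dataclass
class MergedNetwork:
    graph: InteractionGraph
    provenance: dict[str, str]
    """Retained node -> 'compound' | 'disease' | 'shared'."""
    missing_seeds: set[str]


def merge_target_networks(
    compound_targets: set[str],
    disease_targets: set[str],
    background: InteractionGraph,
) -> MergedNetwork:
    """Merge compound-target and disease-target PPI networks.

    The merged network is the background-induced subgraph on the union of
    both seed sets (isolates dropped); each retained node is labelled by
    which seed set(s) it came from.
    """
    if not compound_targets or not disease_targets:
        raise ValidationError("both target sets must be non-empty")
    induced = induced_ppi_subgraph(
        background, compound_targets | disease_targets, drop_isolated=True
    )
    prov: dict[str, str] = {}
    for n in induced.graph.nodes:
        in_c, in_d = n in compound_targets, n in disease_targets
        prov[n] = "shared" if (in_c and in_d) else ("compound" if in_c else "disease")
    induced.graph.node_kind.update({n: "gene" for n in induced.graph.nodes})
    return MergedNetwork(
        graph=induced.graph, provenance=prov, missing_seeds=induced.missing_seeds
    )


def shared_targets(compound_targets: set[str], disease_targets: set[str]) -> set[str]:
    """Genes targeted by the herb's compounds AND implicated in the disease."""
    return set(compound_targets) & set(disease_targets)
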