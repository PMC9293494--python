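"""Seeded generators for every pipeline input, with known ground truth.

Real inputs to a network-pharmacology study (compound ADME tables,
compound-target links, disease gene lists, a background interactome,
annotation collections) come from databases that cannot be shipped. These
generators emulate each input's load-bearing statistical features — OB/DL
values straddling the activity thresholds, power-law target counts per
compound, a heavy-tailed (preferential-attachment) interactome with
planted hub nodes and one planted near-clique module, and an annotation
collection with one planted enriched term — so every stage can be tested
against a known answer.

All randomness flows from one integer seed through per-generator
substreams (``default_rng([seed, stream])``), so outputs are byte-stable
per seed and partial re-runs do not disturb one another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .graph import InteractionGraph
from .io import (
    AnnotationCollection,
    CompoundRecord,
    TargetAssociation,
    write_compound_table,
    write_gmt,
    write_graph,
)

__all__ = [
    "SimulationConfig",
    "StudyBundle",
    "simulate_compounds",
    "simulate_interactome",
    "simulate_associations",
    "simulate_annotations",
    "simulate_study",
]

_STREAM_COMPOUNDS = 1
_STREAM_INTERACTOME = 2
_STREAM_ASSOCIATIONS = 3
_STREAM_ANNOTATIONS = 4
_STREAM_DISEASE = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic inputs.

    OB is drawn from a normal truncated at 0, centred near the activity
    threshold region so the screen is non-trivial; DL from a
    Beta(dl_alpha, dl_beta) on [0, 1]. The interactome grows by
    preferential attachment (``attach_m`` edges per new gene), then
    ``n_hubs`` planted hubs each receive ``hub_extra_degree`` extra random
    edges, and one near-clique module of ``module_size`` fresh genes is
    wired at ``module_density`` internally with one sparse edge per
    member to the base graph.
    """

    seed: int = 0
    n_compounds: int = 40
    ob_mean: float = 32.0
    ob_sd: float = 12.0
    dl_alpha: float = 2.0
    dl_beta: float = 5.0
    n_genes: int = 300
    attach_m: int = 2
    n_hubs: int = 5
    hub_extra_degree: int = 40
    module_size: int = 6
    module_density: float = 14.0 / 15.0
    n_terms: int = 50
    planted_term_size: int = 20
    disease_overlap: float = 0.35
    n_disease_genes: int = 60
    assoc_zipf_a: float = 1.8

    def __post_init__(self):
        if self.n_compounds < 0:
            raise ValidationError("n_compounds must be >= 0")
        for name in ("n_genes", "attach_m", "n_hubs", "hub_extra_degree",
                     "n_terms", "planted_term_size", "n_disease_genes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.module_size < 3:
            raise ValidationError("module_size must be >= 3")
        if not 0 < self.module_density <= 1:
            raise ValidationError("module_density must be in (0, 1]")
        if not 0 < self.disease_overlap <= 1:
            raise ValidationError("disease_overlap must be in (0, 1]")
        if self.ob_sd <= 0 or self.dl_alpha <= 0 or self.dl_beta <= 0:
            raise ValidationError("distribution parameters must be positive")
        if self.assoc_zipf_a <= 1:
            raise ValidationError("assoc_zipf_a must be > 1")
        n_internal = round(self.module_density * self.module_size * (self.module_size - 1) / 2)
        if n_internal < self.module_size - 1:
            raise ValidationError(
                "module_density too low to connect a module of this size"
            )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def simulate_compounds(
    cfg: SimulationConfig,
) -> tuple[list[CompoundRecord], set[str]]:
    """Draw a compound table; return it with the analytically known set of
    ids meeting the canonical activity thresholds (OB >= 30, DL >= 0.18)."""
    rng = cfg.rng(_STREAM_COMPOUNDS)
    records: list[CompoundRecord] = []
    truth: set[str] = set()
    for i in range(cfg.n_compounds):
        ob = -1.0
        while ob < 0:  # truncate at zero by redraw
            ob = float(rng.normal(cfg.ob_mean, cfg.ob_sd))
        dl = float(rng.beta(cfg.dl_alpha, cfg.dl_beta))
        mol_id = f"MOL9{i:05d}"
        records.append(CompoundRecord(mol_id=mol_id, name=f"syn-compound-{i:03d}", ob=ob, dl=dl))
        if ob >= 30.0 and dl >= 0.18:
            truth.add(mol_id)
    return records, truth


def _preferential_attachment(
    rng: np.random.Generator, n: int, m: int
) -> InteractionGraph:
    """Grow an n-node graph: seed clique of m+1 nodes, then m degree-
    proportional attachments per new node (no duplicate edges)."""
    g = InteractionGraph()
    m0 = min(m + 1, n)
    names = [_gene_name(i + 1) for i in range(n)]
    for i in range(m0):
        g.add_node(names[i])
        for j in range(i):
            g.add_edge(names[i], names[j])
    repeated: list[str] = []
    for u, v in g.edges():
        repeated.extend((u, v))
    for i in range(m0, n):
        new = names[i]
        targets: set[str] = set()
        while len(targets) < min(m, i):
            pick = repeated[rng.integers(len(repeated))]
            targets.add(pick)
        g.add_node(new)
        for t in sorted(targets):
            g.add_edge(new, t)
            repeated.extend((new, t))
    return g


def simulate_interactome(
    cfg: SimulationConfig,
) -> tuple[InteractionGraph, set[str], set[str]]:
    """Background PPI with planted structure.

    Returns ``(graph, hubs, module_nodes)``: a preferential-attachment
    backbone over ``n_genes`` genes; ``n_hubs`` planted hubs with
    ``hub_extra_degree`` extra uniform-random edges each; and a fresh
    ``module_size``-gene near-clique wired at ``module_density``
    internally plus exactly one edge per member into the backbone.
    """
    rng = cfg.rng(_STREAM_INTERACTOME)
    g = _preferential_attachment(rng, cfg.n_genes, cfg.attach_m)
    base = g.nodes

    hubs = set(str(h) for h in rng.choice(base, size=cfg.n_hubs, replace=False))
    for hub in sorted(hubs):
        added = 0
        while added < cfg.hub_extra_degree:
            other = base[rng.integers(len(base))]
            if other != hub and not g.has_edge(hub, other):
                g.add_edge(hub, other)
                added += 1

    s = cfg.module_size
    module = [_gene_name(cfg.n_genes + i + 1) for i in range(s)]
    pairs = [(module[i], module[j]) for i in range(s) for j in range(i + 1, s)]
    n_internal = round(cfg.module_density * len(pairs))
    for _ in range(200):
        chosen_idx = rng.choice(len(pairs), size=n_internal, replace=False)
        chosen = [pairs[int(i)] for i in sorted(chosen_idx)]
        if _connected(module, chosen):
            break
    else:  # pragma: no cover - density >= spanning requirement retries out fast
        raise ValidationError("could not draw a connected module at this density")
    for n in module:
        g.add_node(n)
    for u, v in chosen:
        g.add_edge(u, v)
    for n in module:  # one sparse anchor edge each into the backbone
        g.add_edge(n, base[rng.integers(len(base))])
    return g, hubs, set(module)


def _connected(nodes: list[str], edges: list[tuple[str, str]]) -> bool:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(nodes)


def simulate_associations(
    cfg: SimulationConfig,
    records: list[CompoundRecord],
    gene_pool: list[str],
) -> list[TargetAssociation]:
    """Compound->target links with power-law (Zipf) target counts."""
    rng = cfg.rng(_STREAM_ASSOCIATIONS)
    cap = min(40, len(gene_pool))
    assoc: list[TargetAssociation] = []
    for rec in records:
        count = min(int(rng.zipf(cfg.assoc_zipf_a)), cap)
        targets = rng.choice(gene_pool, size=count, replace=False)
        for t in sorted(str(x) for x in targets):
            assoc.append(TargetAssociation(rec.mol_id, t, source="synthetic"))
    return assoc


def simulate_annotations(
    cfg: SimulationConfig, key_genes: set[str], gene_pool: list[str] | None = None
) -> tuple[AnnotationCollection, str]:
    """Annotation collection with one planted enriched term.

    The planted term is ``key_genes`` padded with random genes up to
    ``planted_term_size``; the other ``n_terms - 1`` terms are uniform
    draws from the gene namespace. The universe is the whole namespace.
    """
    rng = cfg.rng(_STREAM_ANNOTATIONS)
    if gene_pool is None:
        gene_pool = [_gene_name(i + 1) for i in range(cfg.n_genes + cfg.module_size)]
    if not key_genes <= set(gene_pool):
        raise ValidationError("key_genes must lie inside the gene namespace")
    if cfg.planted_term_size < len(key_genes):
        raise ValidationError("planted_term_size smaller than the key gene set")

    planted_idx = int(rng.integers(cfg.n_terms))
    planted_id = f"TERM{planted_idx:03d}"
    padding_pool = sorted(set(gene_pool) - key_genes)
    n_pad = cfg.planted_term_size - len(key_genes)
    padding = rng.choice(padding_pool, size=n_pad, replace=False) if n_pad else []
    planted_genes = set(key_genes) | {str(x) for x in padding}

    terms: dict[str, tuple[str, set[str]]] = {}
    for i in range(cfg.n_terms):
        tid = f"TERM{i:03d}"
        if i == planted_idx:
            terms[tid] = ("synthetic planted term", planted_genes)
        else:
            size = int(rng.integers(10, 41))
            genes = rng.choice(gene_pool, size=min(size, len(gene_pool)), replace=False)
            terms[tid] = ("synthetic term", {str(x) for x in genes})
    return AnnotationCollection(terms=terms, universe=set(gene_pool)), planted_id


@dataclass
class StudyBundle:
    """Paths to a written synthetic study plus its ground truth."""

    directory: Path
    compounds: Path
    associations: Path
    disease_genes: Path
    background_ppi: Path
    annotations: Path
    truth_path: Path
    truth: dict = field(default_factory=dict)


def simulate_study(cfg: SimulationConfig, outdir: str | Path) -> StudyBundle:
    """Write a complete synthetic study into ``outdir``.

    Files: ``compounds.tsv``, ``assoc.tsv``, ``disease_genes.txt``,
    ``ppi.tsv``, ``terms.gmt``, ``truth.json``. The disease gene list
    contains the planted module genes and hubs (planted structures are
    disease-associated by construction), a ``disease_overlap`` fraction
    drawn from the compound targets, and random padding up to
    ``n_disease_genes``. The annotation collection plants one term around
    the hub and module genes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records, active_truth = simulate_compounds(cfg)
    graph, hubs, module_nodes = simulate_interactome(cfg)
    base_genes = [n for n in graph.nodes if n not in module_nodes]
    assoc = simulate_associations(cfg, records, base_genes)

    rng = cfg.rng(_STREAM_DISEASE)
    compound_targets = sorted({a.gene for a in assoc})
    disease: set[str] = set(module_nodes) | hubs
    n_overlap = min(round(cfg.disease_overlap * cfg.n_disease_genes), len(compound_targets))
    if n_overlap:
        disease |= {str(x) for x in rng.choice(compound_targets, size=n_overlap, replace=False)}
    rest = sorted(set(base_genes) - disease)
    while len(disease) < cfg.n_disease_genes and rest:
        disease.add(rest.pop(int(rng.integers(len(rest)))))

    planted_seed_genes = hubs | module_nodes
    annotations, planted_term = simulate_annotations(
        cfg, planted_seed_genes, gene_pool=list(graph.nodes)
    )

    paths = StudyBundle(
        directory=outdir,
        compounds=outdir / "compounds.tsv",
        associations=outdir / "assoc.tsv",
        disease_genes=outdir / "disease_genes.txt",
        background_ppi=outdir / "ppi.tsv",
        annotations=outdir / "terms.gmt",
        truth_path=outdir / "truth.json",
    )
    write_compound_table(records, paths.compounds)
    with open(paths.associations, "w", encoding="utf-8") as fh:
        fh.write("mol_id\tgene\tsource\n")
        for a in assoc:
            fh.write(f"{a.mol_id}\t{a.gene}\t{a.source}\n")
    with open(paths.disease_genes, "w", encoding="utf-8") as fh:
        for gene in sorted(disease):
            fh.write(f"{gene}\tsynthetic\n")
    write_graph(graph, paths.background_ppi, format="edge-list")
    write_gmt(annotations, paths.annotations)

    truth = {
        "active_compounds": sorted(active_truth),
        "hubs": sorted(hubs),
        "module_nodes": sorted(module_nodes),
        "planted_term": planted_term,
        "config": asdict(cfg),
    }
    with open(paths.truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.truth = truth
    return paths
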