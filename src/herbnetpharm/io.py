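"""Domain records and file formats used throughout the pipeline.

All inputs are plain text (UTF-8, ``#`` comments): compound tables
(TSV/CSV with oral-bioavailability and drug-likeness columns), two-column
edge lists for the background interactome, SIF and GraphML network exports,
GMT annotation collections, and one-symbol-per-line gene lists.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

from .errors import ConfigurationError, ParseError, ValidationError
from .graph import InteractionGraph

__all__ = [
    "CompoundRecord",
    "TargetAssociation",
    "GeneSetRecord",
    "AnnotationCollection",
    "normalize_gene_symbol",
    "read_compound_table",
    "write_compound_table",
    "read_target_associations",
    "read_gene_list",
    "read_edge_list",
    "EdgeListRead",
    "read_sif",
    "read_graphml",
    "write_graph",
    "read_gmt",
    "write_gmt",
    "load_cassiae_semen_compounds",
]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class CompoundRecord:
    """A herbal compound with its ADME screening properties.

    ``ob`` is oral bioavailability in percent (may exceed 100 for some
    database entries); ``dl`` is the dimensionless drug-likeness score in
    [0, 1]. ``is_active`` is unset until the ADME screen runs.
    """

    mol_id: str
    name: str
    ob: float
    dl: float
    is_active: bool = False

    def __post_init__(self):
        if not self.mol_id or not self.mol_id.strip():
            raise ValidationError("compound mol_id must be non-empty")
        if self.ob < 0:
            raise ValidationError(f"{self.mol_id}: ob must be >= 0, got {self.ob}")
        if not 0 <= self.dl <= 1:
            raise ValidationError(f"{self.mol_id}: dl must be in [0, 1], got {self.dl}")


@dataclass(frozen=True)
class TargetAssociation:
    """One compound -> gene-symbol link, tagged with its provenance."""

    mol_id: str
    gene: str
    source: str = "file"


@dataclass
class GeneSetRecord:
    """A labelled, deduplicated set of normalized gene symbols."""

    label: str
    genes: set[str] = field(default_factory=set)
    sources: dict[str, int] = field(default_factory=dict)


@dataclass
class AnnotationCollection:
    """Annotation terms (GO categories, KEGG pathways, ...) as gene sets.

    ``terms`` maps term id -> (description, gene set); ``universe`` is an
    optional explicit background gene set for enrichment.
    """

    terms: dict[str, tuple[str, set[str]]] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self):
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValidationError(f"annotation term {tid!r} has no genes")

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return out


# ---------------------------------------------------------------------------
# gene-symbol canonicalization
# ---------------------------------------------------------------------------


def normalize_gene_symbol(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Canonicalize a gene symbol: strip, uppercase, then alias-map.

    Alias lookup (keys compared case-insensitively) is followed to a fixed
    point so that the function is idempotent even for chained aliases.
    """
    sym = raw.strip().upper()
    if not sym:
        raise ValidationError("gene symbol is empty after stripping whitespace")
    if aliases:
        table = {k.strip().upper(): v.strip().upper() for k, v in aliases.items()}
        seen = {sym}
        while sym in table and table[sym] != sym:
            sym = table[sym]
            if sym in seen:
                raise ValidationError(f"alias cycle involving {raw!r}")
            seen.add(sym)
    return sym


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------

_DEFAULT_COLUMN_GUESSES = {
    "mol_id": ("mol_id", "mol id", "molid", "id"),
    "name": ("name", "mol name", "mol_name", "compound", "molecule name"),
    "ob": ("ob", "ob (%)", "ob(%)", "oral bioavailability"),
    "dl": ("dl", "drug-likeness", "drug likeness"),
}


def _sniff_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ParseError(f"{path}: no header row found")
    delim = "\t" if "\t" in lines[0] else ","
    rows = list(csv.reader(lines, delimiter=delim))
    return rows[0], rows[1:]


def read_compound_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[CompoundRecord]:
    """Read a TSV/CSV compound table into :class:`CompoundRecord` rows.

    ``dialect`` maps the logical names ``mol_id``/``name``/``ob``/``dl`` to
    the file's column headers; without it, common header spellings are
    matched case-insensitively. Row order is preserved; ``is_active`` is
    left unset.
    """
    header, rows = _sniff_rows(path)
    lower = {h.strip().lower(): i for i, h in enumerate(header)}
    idx: dict[str, int] = {}
    for logical in ("mol_id", "name", "ob", "dl"):
        if dialect and logical in dialect:
            wanted = dialect[logical].strip().lower()
            if wanted not in lower:
                raise ConfigurationError(
                    f"{path}: column {dialect[logical]!r} (for {logical!r}) not found"
                )
            idx[logical] = lower[wanted]
        else:
            for guess in _DEFAULT_COLUMN_GUESSES[logical]:
                if guess in lower:
                    idx[logical] = lower[guess]
                    break
            else:
                raise ConfigurationError(f"{path}: no column found for {logical!r}")

    records: list[CompoundRecord] = []
    for rowno, row in enumerate(rows, start=2):
        if len(row) <= max(idx.values()):
            raise ParseError(f"{path}: too few fields", line=rowno)
        try:
            ob = float(row[idx["ob"]])
            dl = float(row[idx["dl"]])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric ob/dl value ({exc})", line=rowno) from None
        records.append(
            CompoundRecord(mol_id=row[idx["mol_id"]].strip(), name=row[idx["name"]].strip(), ob=ob, dl=dl)
        )
    ids = [r.mol_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate mol_id(s): {', '.join(dupes)}")
    return records


def write_compound_table(records: list[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mol_id\tname\tob\tdl\tis_active\n")
        for r in records:
            fh.write(f"{r.mol_id}\t{r.name}\t{r.ob:g}\t{r.dl:g}\t{int(r.is_active)}\n")


def read_target_associations(
    path: str | Path, source: str | None = None
) -> list[TargetAssociation]:
    """Read compound->gene links from a two-column (mol_id, gene) table.

    A third column, if present, overrides the ``source`` tag per row.
    Gene symbols are normalized.
    """
    out: list[TargetAssociation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split("\t") if "\t" in line or "," in line else line.split()
            fields = [f.strip() for f in fields if f.strip()]
            if len(fields) < 2:
                raise ParseError(f"{path}: expected mol_id and gene", line=lineno)
            if fields[0].lower() in ("mol_id", "molid", "compound"):
                continue  # header
            tag = fields[2] if len(fields) > 2 else (source or "file")
            out.append(TargetAssociation(fields[0], normalize_gene_symbol(fields[1]), tag))
    return out


def read_gene_list(path: str | Path, label: str = "genes") -> GeneSetRecord:
    """Read a one-symbol-per-line gene list with optional source tags.

    Lines are ``SYMBOL`` or ``SYMBOL<TAB>source``; symbols are normalized
    and deduplicated; per-source contribution counts are tallied.
    """
    rec = GeneSetRecord(label=label)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                gene = normalize_gene_symbol(fields[0])
            except ValidationError:
                raise ParseError(f"{path}: empty gene symbol", line=lineno) from None
            src = fields[1].strip() if len(fields) > 1 else "unspecified"
            rec.genes.add(gene)
            rec.sources[src] = rec.sources.get(src, 0) + 1
    return rec


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


class EdgeListRead(NamedTuple):
    graph: InteractionGraph
    n_dropped: int
    """Lines dropped or collapsed: self-loops plus duplicate edges."""


def read_edge_list(path: str | Path) -> EdgeListRead:
    """Read a whitespace/tab-separated undirected edge list.

    The first two fields of each non-comment line are the endpoints; extra
    fields are ignored. Self-loops are dropped and duplicate edges (in
    either orientation) collapsed; the count of such lines is reported.
    """
    g = InteractionGraph()
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: edge line needs >= 2 fields", line=lineno)
            u, v = fields[0], fields[1]
            if u == v or g.has_edge(u, v):
                dropped += 1
                g.add_node(u)
                g.add_node(v)
                continue
            g.add_edge(u, v)
    return EdgeListRead(g, dropped)


def read_sif(path: str | Path) -> InteractionGraph:
    """Read a SIF file (``node  type  partner...``); any type token accepted."""
    g = InteractionGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 1:
                g.add_node(fields[0])
            elif len(fields) >= 3:
                for partner in fields[2:]:
                    if partner != fields[0] and not g.has_edge(fields[0], partner):
                        g.add_edge(fields[0], partner)
                    else:
                        g.add_node(fields[0])
                        g.add_node(partner)
            else:
                raise ParseError(f"{path}: SIF line needs 1 or >= 3 fields", line=lineno)
    return g


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def read_graphml(path: str | Path) -> InteractionGraph:
    """Read an (undirected) GraphML file written by :func:`write_graph`."""
    tree = ET.parse(path)
    ns = {"g": _GRAPHML_NS}
    g = InteractionGraph()
    kind_keys = {
        k.get("id")
        for k in tree.findall("g:key", ns)
        if k.get("attr.name") == "kind"
    }
    for node in tree.findall(".//g:node", ns):
        nid = node.get("id")
        g.add_node(nid)
        for data in node.findall("g:data", ns):
            if data.get("key") in kind_keys and data.text:
                g.node_kind[nid] = data.text
    for edge in tree.findall(".//g:edge", ns):
        u, v = edge.get("source"), edge.get("target")
        if u != v and not g.has_edge(u, v):
            g.add_edge(u, v)
    return g


def write_graph(g: InteractionGraph, path: str | Path, format: str = "sif") -> None:
    """Export a graph as ``sif``, ``graphml`` or ``edge-list``.

    SIF uses the single interaction type ``pp``; isolated nodes are written
    as bare single-field lines so the node set round-trips.
    """
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            written: set[str] = set()
            for u, v in sorted(g.edges()):
                fh.write(f"{u}\tpp\t{v}\n")
                written.update((u, v))
            for n in g.nodes:
                if n not in written:
                    fh.write(f"{n}\n")
    elif format == "edge-list":
        with open(path, "w", encoding="utf-8") as fh:
            written = set()
            for u, v in sorted(g.edges()):
                fh.write(f"{u}\t{v}\n")
                written.update((u, v))
            for n in g.nodes:
                if n not in written:
                    # degenerate but reloadable: self-pair is dropped on read
                    fh.write(f"{n}\t{n}\n")
    elif format == "graphml":
        root = ET.Element("graphml", xmlns=_GRAPHML_NS)
        key = ET.SubElement(
            root, "key", id="d0", attrib={"for": "node", "attr.name": "kind", "attr.type": "string"}
        )
        graph = ET.SubElement(root, "graph", id="G", edgedefault="undirected")
        for n in g.nodes:
            node = ET.SubElement(graph, "node", id=n)
            if n in g.node_kind:
                data = ET.SubElement(node, "data", key=key.get("id"))
                data.text = g.node_kind[n]
        for i, (u, v) in enumerate(sorted(g.edges())):
            ET.SubElement(graph, "edge", id=f"e{i}", source=u, target=v)
        ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)
    else:
        raise ConfigurationError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------------------
# GMT annotation collections
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: GMT line needs term, description, >=1 gene", line=lineno)
            tid = fields[0].strip()
            if tid in terms:
                raise ValidationError(f"{path}: duplicate term id {tid!r} at line {lineno}")
            genes = {normalize_gene_symbol(f) for f in fields[2:] if f.strip()}
            if not genes:
                raise ParseError(f"{path}: term {tid!r} has no genes", line=lineno)
            terms[tid] = (fields[1].strip(), genes)
    return AnnotationCollection(terms=terms)


def write_gmt(annotations: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid, (desc, genes) in annotations.terms.items():
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# packaged reference data
# ---------------------------------------------------------------------------


def load_cassiae_semen_compounds() -> list[CompoundRecord]:
    """The 13 Cassiae semen compounds with their published TCMSP oral
    bioavailability (%) and drug-likeness values, shipped with the package."""
    from importlib.resources import files

    path = files("herbnetpharm").joinpath("data/cassiae_semen_compounds.tsv")
    return read_compound_table(str(path))
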