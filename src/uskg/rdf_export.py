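"""RDF/OWL representation and graph-file export of a simple knowledge graph.

The extracted triples map onto a small OWL-style ontology: part-whole
facts ("has") become class/subclass pairs (a portal vein is modelled as a
subclass of liver tissue), attribute-valued facts ("show", "status")
become named individuals typed by their attribute class, and any other
relation is kept as a plain object-property fact.  Serialization goes
through rdflib (RDF/XML or Turtle) with deterministic triple ordering so
re-emission is byte-stable; GraphML export supports network viewers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import rdflib
from rdflib import OWL, RDF, RDFS, Namespace, URIRef

from .extraction import SimpleKG

logger = logging.getLogger(__name__)

DEFAULT_BASE = "http://example.org/ultrasound#"

#: relation -> ontology construct; anything absent maps to "fact".
DEFAULT_MAPPING_POLICY: Mapping[str, str] = {
    "has": "subclass",
    "show": "individual",
    "status": "individual",
}


class CyclicHierarchyError(ValueError):
    """Raised when part-whole ("has") triples form a subclass cycle."""

    def __init__(self, path):
        self.path = list(path)
        super().__init__("cyclic class hierarchy: " + " -> ".join(self.path))


@dataclass
class OntologyGraph:
    """Classes, subclass axioms, properties, individuals and plain facts."""

    classes: set[str] = field(default_factory=set)
    subclass_axioms: set[tuple[str, str]] = field(default_factory=set)
    object_properties: set[str] = field(default_factory=set)
    individuals: set[tuple[str, str]] = field(default_factory=set)
    fact_triples: set[tuple[str, str, str]] = field(default_factory=set)

    @property
    def n_elements(self) -> int:
        """One ontology element per source triple: axiom, typing or fact."""
        return (len(self.subclass_axioms) + len(self.individuals)
                + len(self.fact_triples))


def sanitize_identifier(text: str) -> str:
    """Turn an entity/relation text into an IRI-safe local name.

    Spaces become underscores; characters outside ``[A-Za-z0-9_-]`` are
    dropped (logged when that actually changes the name).
    """
    candidate = text.strip().replace(" ", "_")
    cleaned = re.sub(r"[^0-9A-Za-z_\-一-鿿]", "", candidate)
    if not cleaned:
        cleaned = "term"
    if cleaned != candidate:
        logger.info("sanitized identifier %r -> %r", text, cleaned)
    return cleaned


def to_ontology(skg: SimpleKG,
                mapping_policy: Mapping[str, str] | None = None
                ) -> OntologyGraph:
    """Map SKG triples to ontology elements (one element per triple).

    Placeholder-headed triples must be completed or dropped first.  A cycle
    in the subclass ("has") hierarchy raises ``CyclicHierarchyError`` with
    the offending path.
    """
    policy = dict(DEFAULT_MAPPING_POLICY if mapping_policy is None
                  else mapping_policy)
    if any(t.is_placeholder for t in skg.triples):
        raise ValueError(
            "SKG still contains placeholder heads; run completion or drop "
            "them before ontology export")
    onto = OntologyGraph()
    for t in skg.triples:
        head = sanitize_identifier(t.head)
        rel = sanitize_identifier(t.relation)
        tail = sanitize_identifier(t.tail)
        construct = policy.get(t.relation, "fact")
        if construct == "subclass":
            onto.classes |= {head, tail}
            onto.subclass_axioms.add((tail, head))  # tail is the part/child
        elif construct == "individual":
            onto.classes.add(head)
            onto.individuals.add((tail, head))
        else:
            onto.classes |= {head, tail}
            onto.object_properties.add(rel)
            onto.fact_triples.add((head, rel, tail))
    cycle_graph = nx.DiGraph(list(onto.subclass_axioms))
    try:
        cycle = nx.find_cycle(cycle_graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = [edge[0] for edge in cycle] + [cycle[0][0]]
        raise CyclicHierarchyError(path)
    return onto


def to_rdflib_graph(onto: OntologyGraph,
                    base: str = DEFAULT_BASE) -> rdflib.Graph:
    """Deterministically build an rdflib graph for the ontology."""
    ns = Namespace(base)
    g = rdflib.Graph()
    g.bind("", ns)
    g.bind("owl", OWL)
    triples: list[tuple[URIRef, URIRef, URIRef]] = []
    triples.append((URIRef(base.rstrip("#")), RDF.type, OWL.Ontology))
    for c in sorted(onto.classes):
        triples.append((ns[c], RDF.type, OWL.Class))
    for p in sorted(onto.object_properties):
        triples.append((ns[p], RDF.type, OWL.ObjectProperty))
    for child, parent in sorted(onto.subclass_axioms):
        triples.append((ns[child], RDFS.subClassOf, ns[parent]))
    for ind, cls in sorted(onto.individuals):
        triples.append((ns[ind], RDF.type, OWL.NamedIndividual))
        triples.append((ns[ind], RDF.type, ns[cls]))
    for s, p, o in sorted(onto.fact_triples):
        triples.append((ns[s], ns[p], ns[o]))
    for tr in triples:
        g.add(tr)
    return g


def from_rdflib_graph(g: rdflib.Graph,
                      base: str = DEFAULT_BASE) -> OntologyGraph:
    """Parse an rdflib graph (as emitted by ``to_rdflib_graph``) back."""
    def local(term) -> str:
        text = str(term)
        return text[len(base):] if text.startswith(base) else text

    onto = OntologyGraph()
    typed_individuals = set()
    for s in g.subjects(RDF.type, OWL.Class):
        onto.classes.add(local(s))
    for s in g.subjects(RDF.type, OWL.ObjectProperty):
        onto.object_properties.add(local(s))
    for s in g.subjects(RDF.type, OWL.NamedIndividual):
        typed_individuals.add(s)
    for s, o in g.subject_objects(RDFS.subClassOf):
        onto.subclass_axioms.add((local(s), local(o)))
    for s in typed_individuals:
        for cls in g.objects(s, RDF.type):
            if cls not in (OWL.NamedIndividual,):
                onto.individuals.add((local(s), local(cls)))
    ontology_nodes = set(g.subjects(RDF.type, OWL.Ontology))
    known = ({RDF.type, RDFS.subClassOf})
    for s, p, o in g:
        if p in known or s in ontology_nodes:
            continue
        onto.fact_triples.add((local(s), local(p), local(o)))
    return onto


def serialize(onto: OntologyGraph, dialect: str = "xml",
              base: str = DEFAULT_BASE) -> str:
    """Emit the ontology as RDF/XML (default) or Turtle text."""
    if dialect not in ("xml", "turtle"):
        raise ValueError(f"unknown RDF dialect {dialect!r}")
    g = to_rdflib_graph(onto, base)
    return g.serialize(format="pretty-xml" if dialect == "xml" else "turtle")


def parse(document: str, base: str = DEFAULT_BASE) -> OntologyGraph:
    """Parse a previously serialized RDF document back to an OntologyGraph."""
    g = rdflib.Graph()
    fmt = "xml" if document.lstrip().startswith("<") else "turtle"
    g.parse(data=document, format=fmt)
    return from_rdflib_graph(g, base)


def export_graphml(skg: SimpleKG) -> str:
    """Labeled directed graph of the SKG for GraphML viewers.

    Nodes are entities (placeholder included if present), one edge per
    distinct (head, relation, tail) with a multiplicity attribute counting
    duplicates; node ordering is deterministic.
    """
    g = nx.MultiDiGraph()
    counts: dict[tuple[str, str, str], int] = {}
    for t in skg.triples:
        counts[t.spo] = counts.get(t.spo, 0) + 1
    for node in sorted({h for h, _, _ in counts} | {t for _, _, t in counts}):
        g.add_node(node)
    for (h, r, t), mult in sorted(counts.items()):
        g.add_edge(h, t, key=r, relation=r, multiplicity=mult)
    return "\n".join(nx.generate_graphml(g))


def export_dot(skg: SimpleKG) -> str:
    """Minimal DOT rendering (labels on edges), deterministic ordering."""
    lines = ["digraph skg {"]
    counts: dict[tuple[str, str, str], int] = {}
    for t in skg.triples:
        counts[t.spo] = counts.get(t.spo, 0) + 1
    for (h, r, t), mult in sorted(counts.items()):
        label = r if mult == 1 else f"{r} (x{mult})"
        lines.append(f'  "{h}" -> "{t}" [label="{label}"];')
    lines.append("}")
    return "\n".join(lines)
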