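"""Taxonomic concepts, name relations, SKOS/RCC-5 alignment and treatments.

A *taxonomic concept* is the falsifiable theory a taxonomist forms about a
taxon in a publication.  It is simultaneously a SKOS concept (so concept
hierarchies can be expressed with broader/narrower), a bibliographic work
(realized by taxonomic treatments), a Darwin Core taxon, and an operational
taxonomic unit.  Each concept carries at least one *taxonomic concept
label* — "name sec. reference" — and every label identifies exactly one
concept, which is what Linnaean names alone cannot do.

Between names, two patterns are supported: *replacement name* (directed —
the target name should be used instead of the source; chains lead to the
currently used name) and *related name* (symmetric, no preference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from rdflib import Graph, Literal, URIRef

from . import terms as T
from .names import TaxonomicConceptLabelParse
from .terms import DCTERMS, OB, RDF, RDFS, SKOS
from .vocabulary import RCC5


class CardinalityViolation(ValueError):
    """A concept is missing its mandatory concept label."""


class LabelUniquenessViolation(ValueError):
    """A concept label is already attached to a different concept."""


class InvalidEdgeError(ValueError):
    """A name or concept relation violates its constraints."""


@dataclass(frozen=True)
class TaxonomicConcept:
    """A taxonomic concept with ≥1 uniquely-identifying label."""

    id: URIRef
    labels: tuple[TaxonomicConceptLabelParse, ...]
    scientific_name_ids: tuple[URIRef, ...] = ()
    treatment_ids: tuple[URIRef, ...] = ()

    def __post_init__(self):
        if len(self.labels) < 1:
            raise CardinalityViolation(
                "a taxonomic concept needs at least one concept label"
            )


@dataclass(frozen=True)
class NameRelationEdge:
    """A directed replacement-name or (symmetric) related-name edge."""

    source: URIRef
    target: URIRef
    kind: str  # "replacementName" | "relatedName"

    def __post_init__(self):
        if self.kind not in ("replacementName", "relatedName"):
            raise InvalidEdgeError(f"unknown name-relation kind {self.kind!r}")
        if self.source == self.target:
            raise InvalidEdgeError("name relations are irreflexive")


@dataclass(frozen=True)
class RCC5StatementSpec:
    """A reified RCC-5 statement: a disjunction of base relations between
    two concepts, with optional provenance."""

    id: URIRef
    subject: URIRef
    object: URIRef
    relations: frozenset[RCC5]
    source: str | None = None

    def __post_init__(self):
        if self.subject == self.object:
            raise InvalidEdgeError("RCC-5 statements relate distinct concepts")
        if not self.relations:
            raise InvalidEdgeError("RCC-5 relation set must be non-empty")
        if not all(isinstance(r, RCC5) for r in self.relations):
            raise InvalidEdgeError("relations must be RCC-5 vocabulary members")


def _norm_label(s: str) -> str:
    return " ".join(s.split())


def existing_labels(graph: Graph) -> dict[str, URIRef]:
    """Map of normalized label string → owning concept IRI."""
    out: dict[str, URIRef] = {}
    for concept, label_node in graph.subject_objects(T.TAXONOMIC_CONCEPT_LABEL_PROP):
        for lit in graph.objects(label_node, RDFS.label):
            out[_norm_label(str(lit))] = concept
    return out


def add_concept(graph: Graph, c: TaxonomicConcept) -> Graph:
    """Add a taxonomic concept with its labels and name links.

    Enforces the label contract up front: at least one label, and no label
    string already identifying a different concept (labels are unique
    identifiers of concepts).
    """
    taken = existing_labels(graph)
    for lab in c.labels:
        owner = taken.get(_norm_label(lab.verbatim))
        if owner is not None and owner != c.id:
            raise LabelUniquenessViolation(
                f"label {lab.verbatim!r} already identifies {owner}"
            )
    g = graph
    for cls in (T.TAXONOMIC_CONCEPT, SKOS.Concept, T.FRBR.Work,
                T.DWC.Taxon, T.OPERATIONAL_TAXONOMIC_UNIT):
        g.add((c.id, RDF.type, cls))
    for i, lab in enumerate(c.labels):
        label_node = URIRef(f"{c.id}/label/{i}")
        g.add((label_node, RDF.type, T.TAXONOMIC_CONCEPT_LABEL))
        g.add((label_node, RDFS.label, Literal(lab.verbatim)))
        g.add((label_node, OB.secReference, Literal(lab.sec_reference)))
        g.add((c.id, T.TAXONOMIC_CONCEPT_LABEL_PROP, label_node))
        g.add((c.id, T.TAXONOMIC_NAME_PROP, label_node))
    for name_id in c.scientific_name_ids:
        if (name_id, RDF.type, None) not in g:
            g.add((name_id, RDF.type, T.SCIENTIFIC_NAME))
        g.add((c.id, T.SCIENTIFIC_NAME_PROP, name_id))
        g.add((c.id, T.TAXONOMIC_NAME_PROP, name_id))
    for treatment in c.treatment_ids:
        realize_treatment(g, treatment, c.id)
    return g


def assert_name_relation(graph: Graph, e: NameRelationEdge) -> Graph:
    """Assert a name relation; related-name edges are stored symmetrically."""
    for node in (e.source, e.target):
        if (node, None, None) not in graph:
            raise InvalidEdgeError(f"unknown name node {node}")
    prop = T.REPLACEMENT_NAME if e.kind == "replacementName" else T.RELATED_NAME
    graph.add((e.source, prop, e.target))
    if e.kind == "relatedName":
        graph.add((e.target, prop, e.source))
    return graph


@dataclass(frozen=True)
class ResolutionReport:
    """Result of following replacement-name chains from a start name."""

    start: URIRef
    terminals: frozenset[URIRef]
    paths: dict[URIRef, tuple[URIRef, ...]] = field(default_factory=dict)
    cycles: tuple[tuple[URIRef, ...], ...] = ()

    @property
    def has_cycle(self) -> bool:
        return bool(self.cycles)


def replacement_graph(graph: Graph) -> nx.DiGraph:
    dg = nx.DiGraph()
    for s, o in graph.subject_objects(T.REPLACEMENT_NAME):
        dg.add_edge(s, o)
    return dg


def resolve_current_names(graph: Graph, name: URIRef) -> ResolutionReport:
    """Follow replacement-name chains to every currently used name.

    Returns all chain-terminal names reachable from *name* (a name without
    outgoing replacement edges resolves to itself).  Branching chains yield
    all terminals — no precedence is imposed.  Cycles among reachable names
    are reported in the result, never silently broken.
    """
    dg = replacement_graph(graph)
    if name not in dg:
        return ResolutionReport(start=name, terminals=frozenset({name}),
                                paths={name: (name,)})
    reachable = {name} | nx.descendants(dg, name)
    sub = dg.subgraph(reachable)
    cycles = tuple(
        tuple(scc) for scc in nx.strongly_connected_components(sub)
        if len(scc) > 1 or sub.has_edge(next(iter(scc)), next(iter(scc)))
    )
    terminals = frozenset(n for n in reachable if sub.out_degree(n) == 0)
    if not terminals and not cycles:
        terminals = frozenset({name})
    paths: dict[URIRef, tuple[URIRef, ...]] = {}
    for t in terminals:
        paths[t] = tuple(nx.shortest_path(sub, name, t))
    return ResolutionReport(start=name, terminals=terminals,
                            paths=paths, cycles=cycles)


def related_name_neighborhood(graph: Graph, name: URIRef, depth: int) -> frozenset[URIRef]:
    """Names within *depth* hops of *name* over the union of related-name
    and replacement-name edges, treated as undirected.  Excludes the start
    name itself."""
    if depth < 1:
        raise InvalidEdgeError("depth must be >= 1")
    ug = nx.Graph()
    ug.add_node(name)
    for prop in (T.RELATED_NAME, T.REPLACEMENT_NAME):
        for s, o in graph.subject_objects(prop):
            ug.add_edge(s, o)
    if name not in ug:
        return frozenset()
    reached = nx.single_source_shortest_path_length(ug, name, cutoff=depth)
    return frozenset(n for n in reached if n != name)


def assert_skos_relation(graph: Graph, narrower: URIRef, broader: URIRef) -> Graph:
    """Assert a broader/narrower pair between two concepts.

    Multiple simultaneous hierarchies are allowed: a concept may sit under
    different parents contributed by different classifications.
    """
    if narrower == broader:
        raise InvalidEdgeError("a concept cannot be broader than itself")
    for node in (narrower, broader):
        if (node, RDF.type, T.TAXONOMIC_CONCEPT) not in graph:
            raise InvalidEdgeError(f"{node} is not a taxonomic concept in this graph")
    graph.add((narrower, SKOS.broader, broader))
    graph.add((broader, SKOS.narrower, narrower))
    return graph


def assert_rcc5(graph: Graph, s: RCC5StatementSpec) -> Graph:
    """Assert a reified RCC-5 statement between two concepts.

    The relation set encodes disjunctive uncertainty: a singleton set is the
    determinate case, a larger set means "one of these holds".
    """
    g = graph
    g.add((s.id, RDF.type, T.RCC5_STATEMENT))
    g.add((s.id, T.HAS_SUBJECT_CONCEPT, s.subject))
    g.add((s.id, T.HAS_OBJECT_CONCEPT, s.object))
    for rel in s.relations:
        g.add((s.id, T.HAS_RELATION, rel.iri))
    if s.source:
        g.add((s.id, DCTERMS.source, Literal(s.source)))
    return g


def realize_treatment(graph: Graph, treatment: URIRef, concept: URIRef) -> Graph:
    """Assert that a treatment section realizes a taxonomic concept.

    The concept, being a work, may be realized by any number of treatments
    (revisions re-realize earlier concepts)."""
    if (treatment, RDF.type, T.TREATMENT) not in graph:
        raise InvalidEdgeError(f"{treatment} is not a Treatment component")
    if (concept, RDF.type, T.TAXONOMIC_CONCEPT) not in graph:
        raise InvalidEdgeError(f"{concept} is not a taxonomic concept")
    graph.add((treatment, T.FRBR.realizationOf, concept))
    graph.add((concept, T.FRBR.realization, treatment))
    return graph


def attach_habitat(graph: Graph, concept: URIRef, habitat_iri: URIRef | str) -> Graph:
    """Link a concept to an external environment-ontology term via the
    habitat shortcut.  Idempotent; the IRI must be absolute."""
    if (concept, RDF.type, T.TAXONOMIC_CONCEPT) not in graph:
        raise InvalidEdgeError(f"{concept} is not a taxonomic concept")
    iri = str(habitat_iri)
    if "://" not in iri or " " in iri:
        raise InvalidEdgeError(f"malformed habitat IRI {habitat_iri!r}")
    graph.add((concept, T.HABITAT_PROP, URIRef(iri)))
    return graph
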