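"""Building RDF graphs of taxonomic articles.

An article is modeled at two bibliographic levels: the *work* (the abstract
research paper) and its *expression* (the taxonomic article, the version of
record, a subclass of journal article).  The article's content is a tree of
typed document components — treatments, nomenclature sections, materials
examined, keys, checklists — linked by the transitive ``contains`` property,
and name usages are mention nodes contained in sections and linked to the
names they mention.
"""

from __future__ import annotations

import random
import uuid
from dataclasses import dataclass, field

import networkx as nx
from rdflib import Graph, Literal, URIRef
from rdflib.compare import isomorphic, to_isomorphic

from . import terms as T
from .names import TaxonomicNameUsageParse
from .terms import DCTERMS, OB, PRISM, RDF, RDFS
from .vocabulary import StatusClass


class StructuralError(ValueError):
    """The component structure violates the article model (cycle, bad kind)."""


class ReferenceError_(KeyError):
    """A referenced node is absent from the graph."""


class IriMinter:
    """Mints UUID-suffixed IRIs under a namespace.

    With a seed, the UUID stream is deterministic — fixture generation and
    tests rely on this; without one, IRIs are random UUID4s.
    """

    def __init__(self, base: str = str(OB), seed: int | None = None):
        self.base = base
        self._rng = random.Random(seed) if seed is not None else None

    def mint(self, prefix: str = "") -> URIRef:
        if self._rng is not None:
            u = uuid.UUID(int=self._rng.getrandbits(128), version=4)
        else:
            u = uuid.uuid4()
        return URIRef(f"{self.base}{prefix}{u}")


@dataclass(frozen=True)
class ArticleMetadata:
    """Bibliographic metadata for a taxonomic article (work + expression)."""

    title: str
    authors: tuple[str, ...] = ()
    doi: str | None = None
    journal: str | None = None
    work_id: URIRef | None = None
    expression_id: URIRef | None = None

    def __post_init__(self):
        if not self.title:
            raise ValueError("article title must be non-empty")
        if (self.work_id is not None and self.expression_id is not None
                and self.work_id == self.expression_id):
            raise ValueError("work and expression must be distinct nodes")


@dataclass
class DocumentComponent:
    """A node of the article's containment tree, typed by section kind."""

    kind: str
    id: URIRef | None = None
    children: list["DocumentComponent"] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in T.COMPONENT_KINDS:
            raise StructuralError(f"unknown component kind {self.kind!r}")

    def walk(self):
        """Yield (parent, child) edges depth-first; raise on cycles."""
        seen: set[int] = set()

        def rec(node, path):
            if id(node) in path:
                raise StructuralError("cyclic component structure")
            if id(node) in seen:
                raise StructuralError("component appears under two parents")
            seen.add(id(node))
            for child in node.children:
                yield node, child
                yield from rec(child, path | {id(node)})

        yield from rec(self, frozenset())


@dataclass(frozen=True)
class NameUsageNode:
    """A taxonomic name usage: a mention region inside a document component."""

    id: URIRef
    parse: TaxonomicNameUsageParse
    mentioned_name_id: URIRef
    container_id: URIRef


def new_graph() -> Graph:
    """A fresh graph with the package prefix map bound."""
    return T.bind_namespaces(Graph())


def build_article_graph(
    meta: ArticleMetadata,
    root: DocumentComponent,
    graph: Graph | None = None,
    minter: IriMinter | None = None,
) -> Graph:
    """Build the RDF graph of one article.

    The root component must be of kind ``TaxonomicArticle``; it becomes the
    expression node, linked to a work node carrying the abstract metadata.
    Every parent→child edge of the component tree is asserted with
    ``contains`` (transitive by ontology, asserted edges only here) and an
    integer position preserving document order.
    """
    if root.kind != "TaxonomicArticle":
        raise StructuralError("root component must be a TaxonomicArticle")
    g = graph if graph is not None else new_graph()
    minter = minter or IriMinter()

    expression = root.id or minter.mint("article/")
    root.id = expression
    work = meta.work_id or minter.mint("work/")
    if work == expression:
        raise StructuralError("work and expression must be distinct nodes")

    g.add((work, RDF.type, T.FABIO.ResearchPaper))
    g.add((work, DCTERMS.title, Literal(meta.title)))
    g.add((work, T.FRBR.realization, expression))
    g.add((expression, T.FRBR.realizationOf, work))
    g.add((expression, RDF.type, T.TAXONOMIC_ARTICLE))
    g.add((expression, DCTERMS.title, Literal(meta.title)))
    for author in meta.authors:
        g.add((work, DCTERMS.creator, Literal(author)))
        g.add((expression, DCTERMS.creator, Literal(author)))
    if meta.doi:
        g.add((expression, PRISM.doi, Literal(meta.doi)))
    if meta.journal:
        g.add((expression, DCTERMS.isPartOf, Literal(meta.journal)))

    # Walk validates acyclicity before any triple is added for components.
    edges = list(root.walk())
    for parent, child in edges:
        if child.id is None:
            child.id = minter.mint("component/")
    for parent, child in edges:
        g.add((child.id, RDF.type, T.COMPONENT_KINDS[child.kind]))
        g.add((parent.id, T.CONTAINS, child.id))
    parents = {id(p): p for p, _ in edges}
    for parent in parents.values():
        for idx, child in enumerate(parent.children):
            g.add((child.id, T.POSITION_PROP, Literal(idx)))
    return g


def add_name_usage(graph: Graph, usage: NameUsageNode) -> Graph:
    """Attach a name-usage node to its containing component.

    The usage is typed as a taxonomic name usage (hence a mention region),
    contained in its section, and linked with ``mentions`` to the name node
    (typed as a scientific name if not yet typed).  A parsed status, if any,
    is attached as its vocabulary concept.
    """
    container = usage.container_id
    if (container, RDF.type, None) not in graph:
        raise ReferenceError_(f"unknown container {container}")
    g = graph
    g.add((usage.id, RDF.type, T.TAXONOMIC_NAME_USAGE))
    g.add((container, T.CONTAINS, usage.id))
    g.add((usage.id, T.MENTIONS, usage.mentioned_name_id))
    if (usage.mentioned_name_id, RDF.type, None) not in g:
        g.add((usage.mentioned_name_id, RDF.type, T.SCIENTIFIC_NAME))
    g.add((usage.mentioned_name_id, RDFS.label,
           Literal(usage.parse.name.verbatim)))
    g.add((usage.id, RDFS.label, Literal(usage.parse.name.verbatim)))
    if usage.parse.status is not None and usage.parse.status is not StatusClass.UNCLASSIFIED:
        g.add((usage.id, T.TAXONOMIC_STATUS_PROP, usage.parse.status.iri))
        g.add((usage.id, OB.statusVerbatim, Literal(usage.parse.status_verbatim)))
    return g


def contains_graph(graph: Graph) -> nx.DiGraph:
    """The asserted ``contains`` edges as a directed graph."""
    dg = nx.DiGraph()
    for s, o in graph.subject_objects(T.CONTAINS):
        dg.add_edge(s, o)
    return dg


def contains_closure(graph: Graph, materialize: bool = False) -> set[tuple[URIRef, URIRef]]:
    """Transitive closure of the asserted ``contains`` edges.

    Computed on demand; with ``materialize=True`` the inferred pairs are
    also asserted into the graph (off by default so asserted and inferred
    triples stay distinct).
    """
    dg = contains_graph(graph)
    closure = set(nx.transitive_closure(dg, reflexive=False).edges())
    if materialize:
        for a, d in closure:
            graph.add((a, T.CONTAINS, d))
    return closure


def serialize_graph(graph: Graph, destination=None, fmt: str = "turtle"):
    """Serialize to Turtle or RDF/XML (``fmt`` in {"turtle", "rdfxml"})."""
    rdflib_fmt = {"turtle": "turtle", "ttl": "turtle",
                  "rdfxml": "xml", "xml": "xml"}[fmt]
    return graph.serialize(destination=destination, format=rdflib_fmt)


def parse_graph(source, fmt: str | None = None) -> Graph:
    """Parse a Turtle or RDF/XML file/string into a graph.

    Format is guessed from the file suffix when not given.  Malformed input
    raises the parser's error with position diagnostics.
    """
    g = new_graph()
    rdflib_fmt = None
    if fmt is not None:
        rdflib_fmt = {"turtle": "turtle", "ttl": "turtle",
                      "rdfxml": "xml", "xml": "xml"}[fmt]
    g.parse(source, format=rdflib_fmt)
    return g


def roundtrip(graph: Graph, fmt: str = "turtle") -> Graph:
    """Serialize and re-parse a graph; the result is isomorphic."""
    data = serialize_graph(graph, fmt=fmt)
    g = new_graph()
    g.parse(data=data, format={"turtle": "turtle", "rdfxml": "xml"}[fmt])
    return g


def graphs_isomorphic(a: Graph, b: Graph) -> bool:
    """Blank-node-aware RDF graph isomorphism."""
    return isomorphic(a, b) or to_isomorphic(a) == to_isomorphic(b)
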