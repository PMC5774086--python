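"""Core ontology emission and the two controlled vocabularies.

Two small controlled vocabularies sit at the heart of the model:

* the **taxonomic status vocabulary** — the eight recurring kinds of
  nomenclatural/taxonomic act that trail a name usage in print
  ("sp. n.", "comb. n.", "incertae sedis", ...), plus an ``Unclassified``
  fallback for everything else;
* the **RCC-5 vocabulary** — the five base relations of the Region
  Connection Calculus over non-empty sets (equals, proper part, inverse
  proper part, partial overlap, disjoint) used to align taxonomic concepts.

Both are emitted as SKOS concept schemes; the core ontology declares every
registry class and property with its OWL characteristics.
"""

from __future__ import annotations

import enum
import re
from pathlib import Path

import yaml
from rdflib import BNode, Graph, Literal, URIRef

from . import terms as T
from .terms import OB, OWL, RDF, RDFS, SKOS


class InvalidInputError(ValueError):
    """Raised on inputs that violate an operation's precondition."""


class StatusClass(enum.Enum):
    """Classification of a taxonomic status abbreviation.

    The eight named members cover the most common statuses in taxonomic
    journals; ``UNCLASSIFIED`` is the total-function fallback, not a
    vocabulary member.
    """

    TAXONOMIC_UNCERTAINTY = "TaxonomicUncertainty"
    TAXON_DISCOVERY = "TaxonDiscovery"
    REPLACEMENT_NAME = "ReplacementName"
    UNAVAILABLE_NAME = "UnavailableName"
    AVAILABLE_NAME = "AvailableName"
    TYPE_SPECIMEN_DESIGNATION = "TypeSpecimenDesignation"
    TYPE_SPECIES_DESIGNATION = "TypeSpeciesDesignation"
    NEW_OCCURRENCE_RECORD = "NewOccurrenceRecord"
    UNCLASSIFIED = "Unclassified"

    @property
    def iri(self) -> URIRef:
        return OB[self.value]


#: Printed exemplar abbreviation for each status class (used as skos:example).
STATUS_EXEMPLARS = {
    StatusClass.TAXONOMIC_UNCERTAINTY: "incertae sedis",
    StatusClass.TAXON_DISCOVERY: "sp. n.",
    StatusClass.REPLACEMENT_NAME: "comb. n.",
    StatusClass.UNAVAILABLE_NAME: "nomen dubium",
    StatusClass.AVAILABLE_NAME: "stat. rev.",
    StatusClass.TYPE_SPECIMEN_DESIGNATION: "lectotype designation",
    StatusClass.TYPE_SPECIES_DESIGNATION: "type species",
    StatusClass.NEW_OCCURRENCE_RECORD: "new country record",
}

STATUS_COMMENTS = {
    StatusClass.TAXONOMIC_UNCERTAINTY: "Taxonomic uncertainty",
    StatusClass.TAXON_DISCOVERY: "Taxonomic discovery",
    StatusClass.REPLACEMENT_NAME: "Replacement name",
    StatusClass.UNAVAILABLE_NAME: "Unavailable name",
    StatusClass.AVAILABLE_NAME: "Available name",
    StatusClass.TYPE_SPECIMEN_DESIGNATION: "Type specimen designation",
    StatusClass.TYPE_SPECIES_DESIGNATION: "Type species designation",
    StatusClass.NEW_OCCURRENCE_RECORD: "New occurrence record (for region)",
}

# Exemplars plus common orthographic variants.  The replacement-name entries
# include the three patterns new combinations, nomina nova and junior
# synonymies are flagged with in practice.  Extensible at run time via
# extend_status_patterns()/load_status_patterns().
_DEFAULT_PATTERNS: dict[StatusClass, tuple[str, ...]] = {
    StatusClass.TAXONOMIC_UNCERTAINTY: ("incertae sedis",),
    StatusClass.TAXON_DISCOVERY: (
        "sp. n.", "sp. nov.", "n. sp.", "spec. nov.", "gen. n.", "gen. nov.",
    ),
    StatusClass.REPLACEMENT_NAME: (
        "comb. n.", "comb. nov.", "n. comb.", "nomen novum", "nom. nov.",
        "syn. nov.", "syn. n.",
    ),
    StatusClass.UNAVAILABLE_NAME: (
        "nomen dubium", "nom. dub.", "nomen nudum", "nom. nud.",
    ),
    StatusClass.AVAILABLE_NAME: ("stat. rev.", "stat. res.", "nomen protectum"),
    StatusClass.TYPE_SPECIMEN_DESIGNATION: (
        "lectotype designation", "neotype designation", "holotype designation",
    ),
    StatusClass.TYPE_SPECIES_DESIGNATION: (
        "type species", "type species designation",
    ),
    StatusClass.NEW_OCCURRENCE_RECORD: (
        "new country record", "new record", "new province record",
    ),
}

_WS = re.compile(r"\s+")


def normalize_abbreviation(abbrev: str) -> str:
    """Lower-case, collapse whitespace and drop a trailing period."""
    s = _WS.sub(" ", abbrev.strip()).lower()
    return s[:-1] if s.endswith(".") else s


def _build_index(patterns: dict[StatusClass, tuple[str, ...]]) -> dict[str, StatusClass]:
    index: dict[str, StatusClass] = {}
    for status, pats in patterns.items():
        for pat in pats:
            index[normalize_abbreviation(pat)] = status
    return index


_PATTERNS: dict[StatusClass, tuple[str, ...]] = dict(_DEFAULT_PATTERNS)
_INDEX: dict[str, StatusClass] = _build_index(_PATTERNS)


def status_patterns() -> dict[StatusClass, tuple[str, ...]]:
    """The abbreviation patterns currently registered per status class."""
    return dict(_PATTERNS)


def extend_status_patterns(extra: dict[StatusClass | str, list[str] | tuple[str, ...]]) -> None:
    """Register additional abbreviation patterns.

    Keys may be :class:`StatusClass` members or their string values.
    """
    global _INDEX
    for key, pats in extra.items():
        status = key if isinstance(key, StatusClass) else StatusClass(key)
        if status is StatusClass.UNCLASSIFIED:
            raise InvalidInputError("cannot register patterns for the fallback class")
        _PATTERNS[status] = tuple(_PATTERNS.get(status, ())) + tuple(pats)
    _INDEX = _build_index(_PATTERNS)


def load_status_patterns(path: str | Path) -> None:
    """Extend the abbreviation mapping from a YAML file of class → patterns."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    extend_status_patterns(data)


def reset_status_patterns() -> None:
    """Restore the packaged default abbreviation mapping."""
    global _PATTERNS, _INDEX
    _PATTERNS = dict(_DEFAULT_PATTERNS)
    _INDEX = _build_index(_PATTERNS)


def classify_status(abbrev: str) -> StatusClass:
    """Classify a taxonomic status abbreviation.

    Matching is insensitive to case, repeated whitespace and a trailing
    period.  Unknown abbreviations map to ``StatusClass.UNCLASSIFIED``.

    >>> classify_status("sp. n.").value
    'TaxonDiscovery'
    """
    if not abbrev or not abbrev.strip():
        raise InvalidInputError("status abbreviation must be a non-empty string")
    return _INDEX.get(normalize_abbreviation(abbrev), StatusClass.UNCLASSIFIED)


class RCC5(enum.Enum):
    """The five base relations of RCC-5 between non-empty sets."""

    EQ = "equals"
    PP = "properPart"
    PPI = "inverseProperPart"
    PO = "partiallyOverlaps"
    DR = "disjointFrom"

    @property
    def converse(self) -> "RCC5":
        return _CONVERSE[self]

    @property
    def iri(self) -> URIRef:
        return OB[self.value]


_CONVERSE = {
    RCC5.EQ: RCC5.EQ,
    RCC5.PP: RCC5.PPI,
    RCC5.PPI: RCC5.PP,
    RCC5.PO: RCC5.PO,
    RCC5.DR: RCC5.DR,
}

RCC5_LABELS = {
    RCC5.EQ: "equals",
    RCC5.PP: "proper part of",
    RCC5.PPI: "has proper part",
    RCC5.PO: "partially overlaps",
    RCC5.DR: "disjoint from",
}


def _new_graph() -> Graph:
    return T.bind_namespaces(Graph())


def emit_core_ontology() -> Graph:
    """Emit the core ontology: every registry class and property with its
    OWL characteristics and external alignments.

    Includes the subclass axioms tying the model to the publishing
    ontologies (taxonomic articles are journal articles; the section classes
    are discourse elements; a name usage is a mention) and the concept-label
    contract: a taxonomic concept carries at least one concept label, and
    the label property is inverse functional.
    """
    g = _new_graph()
    onto = OB["ontology"]
    g.add((onto, RDF.type, OWL.Ontology))
    g.add((onto, RDFS.label, Literal("Taxonomic publishing and concept ontology")))

    for c in T.REGISTRY.classes:
        g.add((c.iri, RDF.type, OWL.Class))
        g.add((c.iri, RDFS.label, Literal(c.label)))
        if c.comment:
            g.add((c.iri, RDFS.comment, Literal(c.comment)))
        for sup in c.superclasses:
            g.add((c.iri, RDFS.subClassOf, sup))
        for eq in c.equivalent:
            g.add((c.iri, OWL.equivalentClass, eq))

    for p in T.REGISTRY.properties:
        g.add((p.iri, RDF.type, OWL.ObjectProperty))
        g.add((p.iri, RDFS.label, Literal(p.label)))
        if p.transitive:
            g.add((p.iri, RDF.type, OWL.TransitiveProperty))
        if p.symmetric:
            g.add((p.iri, RDF.type, OWL.SymmetricProperty))
        if p.inverse_functional:
            g.add((p.iri, RDF.type, OWL.InverseFunctionalProperty))
        if p.domain is not None:
            g.add((p.iri, RDFS.domain, p.domain))
        if p.range is not None:
            g.add((p.iri, RDFS.range, p.range))
        if p.superproperty is not None:
            g.add((p.iri, RDFS.subPropertyOf, p.superproperty))

    # A taxonomic concept has at least one taxonomic concept label.
    restriction = BNode("conceptLabelMinCardinality")
    g.add((T.TAXONOMIC_CONCEPT, RDFS.subClassOf, restriction))
    g.add((restriction, RDF.type, OWL.Restriction))
    g.add((restriction, OWL.onProperty, T.TAXONOMIC_CONCEPT_LABEL_PROP))
    g.add((restriction, OWL.minCardinality,
           Literal(1, datatype=T.XSD.nonNegativeInteger)))
    return g


def status_vocabulary() -> Graph:
    """The taxonomic status vocabulary as a SKOS concept scheme.

    Exactly eight concepts, each carrying its label, comment and example
    abbreviation literals (the registered patterns).
    """
    g = _new_graph()
    scheme = T.STATUS_SCHEME
    g.add((scheme, RDF.type, SKOS.ConceptScheme))
    g.add((scheme, RDFS.label, Literal("Vocabulary of Taxonomic Statuses")))
    for status, exemplar in STATUS_EXEMPLARS.items():
        node = status.iri
        g.add((node, RDF.type, SKOS.Concept))
        g.add((node, SKOS.inScheme, scheme))
        g.add((node, SKOS.prefLabel, Literal(STATUS_COMMENTS[status], lang="en")))
        g.add((node, RDFS.comment, Literal(STATUS_COMMENTS[status])))
        for pat in _PATTERNS[status]:
            g.add((node, SKOS.example, Literal(pat)))
        g.add((node, SKOS.notation, Literal(exemplar)))
    return g


def rcc5_vocabulary() -> Graph:
    """The RCC-5 vocabulary: a SKOS concept scheme of the five base
    relations, typed as RCC-5 relation terms, with converse links."""
    g = _new_graph()
    scheme = T.RCC5_SCHEME
    g.add((scheme, RDF.type, SKOS.ConceptScheme))
    g.add((scheme, RDF.type, T.RCC5_DICTIONARY))
    g.add((scheme, RDFS.label, Literal("RCC-5 Vocabulary")))
    for rel in RCC5:
        node = rel.iri
        g.add((node, RDF.type, SKOS.Concept))
        g.add((node, RDF.type, T.RCC5_RELATION))
        g.add((node, SKOS.inScheme, scheme))
        g.add((node, SKOS.prefLabel, Literal(RCC5_LABELS[rel], lang="en")))
        g.add((node, SKOS.notation, Literal(rel.name)))
        g.add((node, OB.converseRelation, rel.converse.iri))
    return g
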