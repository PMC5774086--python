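"""Namespaces, term IRIs and the term registry for the taxonomic publishing model.

The model bridges two domains: scholarly publishing (FRBR/FaBiO/DEO document
structure) and biological taxonomy (names, name usages, taxonomic concepts).
All project-minted terms live under a single base namespace; external
alignments (SKOS, Darwin Core, the SPAR ontologies, OBO) keep their own IRIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdflib import Namespace
from rdflib.namespace import DCTERMS, FOAF, OWL, RDF, RDFS, SKOS, XSD  # noqa: F401

# Project base namespace (all minted classes, properties and instances).
OB = Namespace("http://openbiodiv.net/")

# External vocabularies the model aligns with.
FABIO = Namespace("http://purl.org/spar/fabio/")
FRBR = Namespace("http://purl.org/vocab/frbr/core#")
DEO = Namespace("http://purl.org/spar/deo/")
DOCO = Namespace("http://purl.org/spar/doco/")
PO = Namespace("http://www.essepuntato.it/2008/12/pattern#")
DWC = Namespace("http://rs.tdwg.org/dwc/terms/")
DWCIRI = Namespace("http://rs.tdwg.org/dwc/iri/")
OBO = Namespace("http://purl.obolibrary.org/obo/")
PRISM = Namespace("http://prismstandard.org/namespaces/basic/2.0/")

#: Prefix → namespace map bound on every graph the package builds.
NAMESPACES = {
    "": OB,
    "openbiodiv": OB,
    "fabio": FABIO,
    "frbr": FRBR,
    "deo": DEO,
    "doco": DOCO,
    "po": PO,
    "dwc": DWC,
    "dwciri": DWCIRI,
    "obo": OBO,
    "prism": PRISM,
    "skos": SKOS,
    "dcterms": DCTERMS,
    "foaf": FOAF,
    "owl": OWL,
}

# --- Document component classes -------------------------------------------
# Sections a taxonomic article is built from.  A treatment is the section
# that realizes a taxonomic concept; its standard subsections carry
# nomenclature, examined specimens, biology and morphological description.
TREATMENT = OB.Treatment
NOMENCLATURE_SECTION = OB.NomenclatureSection
NOMENCLATURE_HEADING = OB.NomenclatureHeading
NOMENCLATURE_CITATION_LIST = OB.NomenclatureCitationList
MATERIALS_EXAMINED = OB.MaterialsExamined
BIOLOGY_SECTION = OB.BiologySection
DESCRIPTION_SECTION = OB.DescriptionSection
TAXONOMIC_KEY = OB.TaxonomicKey
TAXONOMIC_CHECKLIST = OB.TaxonomicChecklist
TAXONOMIC_NAME_USAGE = OB.TaxonomicNameUsage
TAXONOMIC_ARTICLE = OB.TaxonomicArticle
MENTION = OB.Mention

#: The new section classes introduced for taxonomic articles, with the
#: human-readable comments used in their rdfs:comment annotations.
SECTION_CLASS_COMMENTS = {
    TREATMENT: "Section of a taxonomic article",
    NOMENCLATURE_SECTION: "Subsection of Treatment",
    NOMENCLATURE_HEADING: "Contains a nomenclatural act",
    NOMENCLATURE_CITATION_LIST: "List of citations of related concepts",
    MATERIALS_EXAMINED: "List of examined specimens",
    BIOLOGY_SECTION: "Subsection of Treatment",
    DESCRIPTION_SECTION: "Subsection of Treatment",
    TAXONOMIC_KEY: "Section with an identification key",
    TAXONOMIC_CHECKLIST: "Section with a list of taxa for a region",
    TAXONOMIC_NAME_USAGE: "Mention of a taxonomic name",
}

# --- Name and concept classes ---------------------------------------------
TAXONOMIC_NAME = OB.TaxonomicName
SCIENTIFIC_NAME = OB.ScientificName
TAXONOMIC_CONCEPT_LABEL = OB.TaxonomicConceptLabel
TAXONOMIC_CONCEPT = OB.TaxonomicConcept
OPERATIONAL_TAXONOMIC_UNIT = OB.OperationalTaxonomicUnit

# --- RCC-5 machinery classes ----------------------------------------------
RCC5_DICTIONARY = OB.RCC5Dictionary
RCC5_RELATION = OB.RCC5Relation
RCC5_STATEMENT = OB.RCC5Statement

# --- Properties ------------------------------------------------------------
CONTAINS = OB.contains          # transitive part-whole link between components
MENTIONS = OB.mentions          # document region -> mentioned resource
TAXONOMIC_NAME_PROP = OB.taxonomicName
SCIENTIFIC_NAME_PROP = OB.scientificName
TAXONOMIC_CONCEPT_LABEL_PROP = OB.taxonomicConceptLabel
REPLACEMENT_NAME = OB.replacementName
RELATED_NAME = OB.relatedName
TAXONOMIC_STATUS_PROP = OB.taxonomicStatus
RCC5_PROPERTY = OB.rcc5Property
HAS_SUBJECT_CONCEPT = OB.hasSubjectConcept
HAS_OBJECT_CONCEPT = OB.hasObjectConcept
HAS_RELATION = OB.hasRelation
HABITAT_PROP = OB.habitat       # shortcut for the OBO "has habitat" relation
POSITION_PROP = OB.position     # document order of a component within its parent

#: OBO *has habitat* relation the habitat shortcut specializes.
OBO_HAS_HABITAT = OBO.RO_0002303

#: Vocabulary scheme nodes.
STATUS_SCHEME = OB.TaxonomicStatusTerms
RCC5_SCHEME = OB.RCC5RelationshipTerms


@dataclass(frozen=True)
class PropertyDescriptor:
    """A property with the characteristics the ontology asserts for it."""

    iri: object
    label: str
    transitive: bool = False
    symmetric: bool = False
    inverse_functional: bool = False
    domain: object | None = None
    range: object | None = None
    superproperty: object | None = None


@dataclass(frozen=True)
class ClassDescriptor:
    iri: object
    label: str
    superclasses: tuple = ()
    equivalent: tuple = ()
    comment: str | None = None


def _classes() -> tuple[ClassDescriptor, ...]:
    section = tuple(
        ClassDescriptor(iri, str(iri).rsplit("/", 1)[-1], (DEO.DiscourseElement,), (), comment)
        for iri, comment in SECTION_CLASS_COMMENTS.items()
        if iri != TAXONOMIC_NAME_USAGE
    )
    return section + (
        ClassDescriptor(TAXONOMIC_ARTICLE, "TaxonomicArticle", (FABIO.JournalArticle,)),
        ClassDescriptor(MENTION, "Mention", (DEO.DiscourseElement,),
                        comment="An area of a document that can be considered a mention of something"),
        ClassDescriptor(TAXONOMIC_NAME_USAGE, "TaxonomicNameUsage", (MENTION,),
                        comment=SECTION_CLASS_COMMENTS[TAXONOMIC_NAME_USAGE]),
        ClassDescriptor(TAXONOMIC_NAME, "TaxonomicName", ()),
        ClassDescriptor(SCIENTIFIC_NAME, "ScientificName", (TAXONOMIC_NAME,)),
        ClassDescriptor(TAXONOMIC_CONCEPT_LABEL, "TaxonomicConceptLabel", (TAXONOMIC_NAME,)),
        ClassDescriptor(OPERATIONAL_TAXONOMIC_UNIT, "OperationalTaxonomicUnit", ()),
        ClassDescriptor(
            TAXONOMIC_CONCEPT,
            "TaxonomicConcept",
            (FRBR.Work, SKOS.Concept, OPERATIONAL_TAXONOMIC_UNIT),
            equivalent=(DWC.Taxon,),
            comment="The theory a taxonomist forms about a taxon in a publication",
        ),
        ClassDescriptor(RCC5_DICTIONARY, "RCC5Dictionary", (SKOS.ConceptScheme,)),
        ClassDescriptor(RCC5_RELATION, "RCC5Relation", (SKOS.Concept,)),
        ClassDescriptor(RCC5_STATEMENT, "RCC5Statement", ()),
    )


def _properties() -> tuple[PropertyDescriptor, ...]:
    return (
        PropertyDescriptor(CONTAINS, "contains", transitive=True, superproperty=PO.contains),
        PropertyDescriptor(MENTIONS, "mentions", domain=MENTION),
        PropertyDescriptor(TAXONOMIC_NAME_PROP, "taxonomicName",
                           domain=TAXONOMIC_CONCEPT, range=TAXONOMIC_NAME),
        PropertyDescriptor(SCIENTIFIC_NAME_PROP, "scientificName",
                           domain=TAXONOMIC_CONCEPT, range=SCIENTIFIC_NAME,
                           superproperty=TAXONOMIC_NAME_PROP),
        PropertyDescriptor(TAXONOMIC_CONCEPT_LABEL_PROP, "taxonomicConceptLabel",
                           inverse_functional=True,
                           domain=TAXONOMIC_CONCEPT, range=TAXONOMIC_CONCEPT_LABEL,
                           superproperty=TAXONOMIC_NAME_PROP),
        PropertyDescriptor(REPLACEMENT_NAME, "replacementName",
                           domain=TAXONOMIC_NAME, range=TAXONOMIC_NAME),
        PropertyDescriptor(RELATED_NAME, "relatedName", symmetric=True,
                           domain=TAXONOMIC_NAME, range=TAXONOMIC_NAME),
        PropertyDescriptor(TAXONOMIC_STATUS_PROP, "taxonomicStatus",
                           domain=TAXONOMIC_NAME_USAGE),
        PropertyDescriptor(RCC5_PROPERTY, "rcc5Property",
                           domain=TAXONOMIC_CONCEPT, range=TAXONOMIC_CONCEPT),
        PropertyDescriptor(HAS_SUBJECT_CONCEPT, "hasSubjectConcept",
                           domain=RCC5_STATEMENT, range=TAXONOMIC_CONCEPT),
        PropertyDescriptor(HAS_OBJECT_CONCEPT, "hasObjectConcept",
                           domain=RCC5_STATEMENT, range=TAXONOMIC_CONCEPT),
        PropertyDescriptor(HAS_RELATION, "hasRelation",
                           domain=RCC5_STATEMENT, range=RCC5_RELATION),
        PropertyDescriptor(HABITAT_PROP, "habitat",
                           domain=TAXONOMIC_CONCEPT, superproperty=OBO_HAS_HABITAT),
        PropertyDescriptor(POSITION_PROP, "position"),
    )


@dataclass(frozen=True)
class TermRegistry:
    """Registry of every class and property the model mints.

    A single shared instance (:data:`REGISTRY`) is used throughout the
    package; the dataclass exists so alternative registries (e.g. with extra
    name subclasses) can be constructed for extension.
    """

    namespaces: dict = field(default_factory=lambda: dict(NAMESPACES))
    classes: tuple = field(default_factory=_classes)
    properties: tuple = field(default_factory=_properties)

    def class_iris(self) -> set:
        return {c.iri for c in self.classes}

    def property_iris(self) -> set:
        return {p.iri for p in self.properties}

    def property(self, iri) -> PropertyDescriptor:
        for p in self.properties:
            if p.iri == iri:
                return p
        raise KeyError(iri)


REGISTRY = TermRegistry()

#: Component-kind name → class IRI used by the article builder.  The generic
#: kind maps straight onto the external discourse-element class.
COMPONENT_KINDS = {
    "TaxonomicArticle": TAXONOMIC_ARTICLE,
    "Treatment": TREATMENT,
    "NomenclatureSection": NOMENCLATURE_SECTION,
    "NomenclatureHeading": NOMENCLATURE_HEADING,
    "NomenclatureCitationList": NOMENCLATURE_CITATION_LIST,
    "MaterialsExamined": MATERIALS_EXAMINED,
    "BiologySection": BIOLOGY_SECTION,
    "DescriptionSection": DESCRIPTION_SECTION,
    "TaxonomicKey": TAXONOMIC_KEY,
    "TaxonomicChecklist": TAXONOMIC_CHECKLIST,
    "GenericDiscourseElement": DEO.DiscourseElement,
}


def bind_namespaces(graph):
    """Bind the standard prefix map onto *graph* and return it."""
    for prefix, ns in NAMESPACES.items():
        graph.bind(prefix, ns, override=True)
    return graph
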