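"""Closed-world validation of graphs against the model's testable constraints.

The ontology's axioms (minimum label cardinality, inverse-functional concept
labels, domain/range of the name properties) are declared for OWL
consumers, but under open-world OWL semantics two concepts sharing a label
would be *merged*, not flagged.  The system's intent is the opposite —
concept labels are unique identifiers — so conformance is checked here
closed-world, as explicit validation rules over the asserted triples.

Rules (error severity unless noted):

``concept-min-label``
    every taxonomic concept carries at least one concept label;
``label-unique``
    no normalized label string identifies two concepts;
``scientific-name-domain-range``
    subjects/objects of the scientific-name property are typed
    concept/scientific-name respectively;
``usage-mentions-one``
    every taxonomic name usage mentions exactly one taxonomic name
    (zero → error; several → warning);
``containment-acyclic``
    the document ``contains`` structure has no cycles;
``status-in-vocabulary``
    every asserted taxonomic status is one of the 8 vocabulary concepts;
``rcc5-statement-wellformed``
    every RCC-5 statement has a subject, an object and ≥1 vocabulary
    relation;
``treatment-realization-types``
    realization links between document components and concepts connect a
    treatment to a taxonomic concept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from rdflib import Graph

from . import terms as T
from .terms import RDF, RDFS
from .vocabulary import RCC5, StatusClass

_STATUS_IRIS = frozenset(
    s.iri for s in StatusClass if s is not StatusClass.UNCLASSIFIED
)
_RCC5_IRIS = frozenset(r.iri for r in RCC5)

#: Component classes whose instances participate in the containment check.
_COMPONENT_CLASSES = frozenset(T.COMPONENT_KINDS.values())


@dataclass(frozen=True)
class Violation:
    rule_id: str
    severity: str            # "error" | "warning"
    focus_node: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)
    #: how labels were compared (report metadata)
    label_comparison: str = "normalized-string"

    @property
    def passed(self) -> bool:
        return not any(v.severity == "error" for v in self.violations)

    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    def by_rule(self, rule_id: str) -> list[Violation]:
        return [v for v in self.violations if v.rule_id == rule_id]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "label_comparison": self.label_comparison,
            "violations": [vars(v) for v in self.violations],
        }


def _norm(s: str) -> str:
    return " ".join(str(s).split())


def validate_graph(graph: Graph) -> ValidationReport:
    """Run every rule over *graph* and return a deterministic report.

    Violations are sorted by rule id then focus node, so a fixed graph
    always yields the identical report."""
    violations: list[Violation] = []

    def add(rule, node, message, severity="error"):
        violations.append(Violation(rule, severity, str(node), message))

    concepts = set(graph.subjects(RDF.type, T.TAXONOMIC_CONCEPT))

    # concept-min-label
    for c in concepts:
        if graph.value(c, T.TAXONOMIC_CONCEPT_LABEL_PROP) is None:
            add("concept-min-label", c,
                "taxonomic concept without a taxonomic concept label "
                "(at least one is required)")

    # label-unique (normalized label string identifies exactly one concept)
    owners: dict[str, set] = {}
    for c in concepts:
        for label_node in graph.objects(c, T.TAXONOMIC_CONCEPT_LABEL_PROP):
            for lit in graph.objects(label_node, RDFS.label):
                owners.setdefault(_norm(lit), set()).add(c)
    for label, cs in owners.items():
        if len(cs) > 1:
            for c in cs:
                add("label-unique", c,
                    f"concept label {label!r} identifies {len(cs)} concepts")

    # scientific-name-domain-range
    for s, o in graph.subject_objects(T.SCIENTIFIC_NAME_PROP):
        if (s, RDF.type, T.TAXONOMIC_CONCEPT) not in graph:
            add("scientific-name-domain-range", s,
                "subject of the scientific-name property is not a taxonomic concept")
        if (o, RDF.type, T.SCIENTIFIC_NAME) not in graph:
            add("scientific-name-domain-range", o,
                "object of the scientific-name property is not a scientific name")

    # usage-mentions-one
    for usage in graph.subjects(RDF.type, T.TAXONOMIC_NAME_USAGE):
        targets = list(graph.objects(usage, T.MENTIONS))
        if len(targets) == 0:
            add("usage-mentions-one", usage,
                "taxonomic name usage mentions no taxonomic name")
        elif len(targets) > 1:
            add("usage-mentions-one", usage,
                f"taxonomic name usage mentions {len(targets)} names",
                severity="warning")

    # containment-acyclic
    dg = nx.DiGraph()
    for s, o in graph.subject_objects(T.CONTAINS):
        dg.add_edge(s, o)
    try:
        cycle = nx.find_cycle(dg)
    except nx.NetworkXNoCycle:
        cycle = []
    for edge in cycle:
        add("containment-acyclic", edge[0],
            "document component participates in a containment cycle")

    # status-in-vocabulary
    for usage, status in graph.subject_objects(T.TAXONOMIC_STATUS_PROP):
        if status not in _STATUS_IRIS:
            add("status-in-vocabulary", usage,
                f"taxonomic status {status} is not one of the 8 vocabulary concepts")

    # rcc5-statement-wellformed
    for stmt in graph.subjects(RDF.type, T.RCC5_STATEMENT):
        subj = graph.value(stmt, T.HAS_SUBJECT_CONCEPT)
        obj = graph.value(stmt, T.HAS_OBJECT_CONCEPT)
        rels = [r for r in graph.objects(stmt, T.HAS_RELATION)]
        problems = []
        if subj is None:
            problems.append("no subject concept")
        if obj is None:
            problems.append("no object concept")
        if not any(r in _RCC5_IRIS for r in rels):
            problems.append("no RCC-5 vocabulary relation")
        if problems:
            add("rcc5-statement-wellformed", stmt,
                "malformed RCC-5 statement: " + ", ".join(problems))

    # treatment-realization-types
    for s, o in graph.subject_objects(T.FRBR.realizationOf):
        s_component = any((s, RDF.type, cls) in graph for cls in _COMPONENT_CLASSES)
        o_concept = (o, RDF.type, T.TAXONOMIC_CONCEPT) in graph
        if s_component and (s, RDF.type, T.TREATMENT) not in graph and o_concept:
            add("treatment-realization-types", s,
                "non-treatment component asserted as realization of a concept")
        elif (s, RDF.type, T.TREATMENT) in graph and not o_concept:
            # articles realize works; treatments must realize concepts
            add("treatment-realization-types", s,
                "treatment realizes a node that is not a taxonomic concept")

    violations.sort(key=lambda v: (v.rule_id, v.focus_node, v.message))
    return ValidationReport(violations=violations)
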