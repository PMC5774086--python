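"""Deterministic synthetic fixtures: articles, names, concepts, RCC-5 nets.

The generator produces graphs with the same *shapes* as real taxonomic
literature — article component trees with treatments and their standard
subsections, pronounceable pseudo-Latin names with statuses, replacement
DAGs, concepts with unique "name sec. reference" labels arranged in one or
more parallel hierarchies, and RCC-5 statements — without any statistical
realism about journal sizes or rank distributions.  Everything is a pure
function of the spec (same seed ⇒ byte-identical serialization).

Violations can be injected deliberately; every injection is recorded in the
returned manifest, which doubles as the ground-truth oracle for validator
recall tests.  RCC-5 statements are read off a concrete set assignment over
a small universe, so clean fixtures are satisfiable by construction.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

from rdflib import Graph, Literal, URIRef

from . import terms as T
from .article import (ArticleMetadata, DocumentComponent, NameUsageNode,
                      add_name_usage, build_article_graph, new_graph)
from .concepts import (NameRelationEdge, RCC5StatementSpec, TaxonomicConcept,
                       add_concept, assert_name_relation, assert_rcc5,
                       assert_skos_relation, realize_treatment)
from .names import (ScientificName, TaxonomicConceptLabelParse,
                    TaxonomicNameUsageParse, format_name)
from .rcc5 import relation_between
from .terms import OB, RDF, RDFS
from .vocabulary import RCC5, StatusClass, status_patterns


class FixtureSpecError(ValueError):
    """The fixture spec is internally inconsistent."""


#: Violation kinds the generator can inject, with the validator rule each
#: one trips ("replacement-cycle" is flagged by chain resolution instead).
INJECTION_RULES = {
    "missing-label": "concept-min-label",
    "shared-label": "label-unique",
    "scientific-name-domain": "scientific-name-domain-range",
    "usage-mentions-none": "usage-mentions-one",
    "containment-cycle": "containment-acyclic",
    "bad-status": "status-in-vocabulary",
    "rcc5-malformed": "rcc5-statement-wellformed",
    "realization-mismatch": "treatment-realization-types",
    "replacement-cycle": None,
}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_articles: int = 2
    n_treatments_per_article: int = 3
    n_names: int = 20
    p_replacement: float = 0.15
    p_related: float = 0.10
    n_concepts: int = 8
    n_hierarchies: int = 1
    rcc5_density: float = 0.3
    injections: tuple[str, ...] = ()

    def __post_init__(self):
        for p in (self.p_replacement, self.p_related, self.rcc5_density):
            if not 0.0 <= p <= 1.0:
                raise FixtureSpecError("probabilities must lie in [0, 1]")
        for n in (self.n_articles, self.n_treatments_per_article,
                  self.n_names, self.n_concepts, self.n_hierarchies):
            if n < 0:
                raise FixtureSpecError("counts must be non-negative")
        unknown = set(self.injections) - set(INJECTION_RULES)
        if unknown:
            raise FixtureSpecError(f"unknown injection kinds {sorted(unknown)}")
        need_two_concepts = {"shared-label"}
        if need_two_concepts & set(self.injections) and self.n_concepts < 2:
            raise FixtureSpecError("shared-label injection needs >= 2 concepts")
        if "replacement-cycle" in self.injections and self.n_names < 2:
            raise FixtureSpecError("replacement-cycle injection needs >= 2 names")
        if ({"scientific-name-domain", "bad-status"} & set(self.injections)
                and self.n_names < 1):
            raise FixtureSpecError("name injections need >= 1 name")
        if ({"missing-label", "rcc5-malformed"} & set(self.injections)
                and self.n_concepts < 1):
            raise FixtureSpecError("concept injections need >= 1 concept")
        if ({"containment-cycle", "usage-mentions-none", "bad-status",
             "realization-mismatch"} & set(self.injections)
                and (self.n_articles < 1 or self.n_treatments_per_article < 1)):
            raise FixtureSpecError("article injections need >= 1 treatment")


_SYLLABLES = ["ba", "ca", "da", "fe", "ga", "he", "ki", "la", "mi", "no",
              "po", "ra", "su", "ta", "ve", "xi", "zo", "lu", "mer", "tan"]
_AUTH_SYLLABLES = ["Bor", "Del", "Fra", "Gol", "Hart", "Ives", "Kova",
                   "Lind", "Mora", "Nie", "Olse", "Petr", "Sand", "Thor"]


def _latin_word(rng: random.Random, n_syll: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))


def random_scientific_name(rng: random.Random) -> ScientificName:
    """A pronounceable pseudo-Latin name with optional authorship parts."""
    genus = _latin_word(rng, rng.randint(2, 4)).capitalize()
    specific = _latin_word(rng, rng.randint(2, 4)) if rng.random() < 0.85 else None
    marker = infra = None
    if specific and rng.random() < 0.15:
        marker = rng.choice(["var.", "subsp."])
        infra = _latin_word(rng, rng.randint(2, 3))
    authorship = year = None
    parenthesized = year_comma = False
    if rng.random() < 0.8:
        authorship = rng.choice(_AUTH_SYLLABLES) + rng.choice(["v", "sen", "mann", "er"])
        if rng.random() < 0.85:
            year = rng.randint(1758, 2020)
            year_comma = rng.random() < 0.5
        parenthesized = year is not None and rng.random() < 0.2
        if parenthesized:
            year_comma = True
    return ScientificName(
        genus=genus, specific_epithet=specific,
        infraspecific_marker=marker, infraspecific_epithet=infra,
        authorship=authorship, year=year,
        parenthesized_authorship=parenthesized, year_comma=year_comma,
    )


def _component_tree(rng: random.Random, spec: FixtureSpec, a: int):
    """One article's component tree per the section grammar: each treatment
    gets a nomenclature section; other subsections are optional."""
    treatments = []
    for t in range(spec.n_treatments_per_article):
        nomen_children = [DocumentComponent("NomenclatureHeading")]
        if rng.random() < 0.5:
            nomen_children.append(DocumentComponent("NomenclatureCitationList"))
        children = [DocumentComponent("NomenclatureSection", children=nomen_children)]
        for kind in ("MaterialsExamined", "DescriptionSection", "BiologySection"):
            if rng.random() < 0.5:
                children.append(DocumentComponent(kind))
        treatments.append(DocumentComponent("Treatment", children=children))
    extras = []
    if rng.random() < 0.3:
        extras.append(DocumentComponent("TaxonomicKey"))
    if rng.random() < 0.3:
        extras.append(DocumentComponent("TaxonomicChecklist"))
    root = DocumentComponent(
        "TaxonomicArticle",
        id=OB[f"fixture/article/{a}"],
        children=treatments + extras,
    )
    return root, treatments


def gen_fixture(spec: FixtureSpec) -> tuple[Graph, dict]:
    """Generate a fixture graph and its manifest.

    The manifest records entity IRIs (articles, treatments, names, usages,
    concepts, RCC-5 statements), the replacement/related edges, the
    concrete RCC-5 ground-truth assignment, and one entry per injected
    violation with the validator rule it must trip and its focus nodes.
    """
    rng = random.Random(spec.seed)
    g = new_graph()
    manifest: dict = {
        "seed": spec.seed,
        "entities": {},
        "replacement_edges": [],
        "related_edges": [],
        "hierarchies": [],
        "injections": [],
    }

    # --- articles --------------------------------------------------------
    articles, treatments = [], []
    for a in range(spec.n_articles):
        root, art_treatments = _component_tree(rng, spec, a)
        meta = ArticleMetadata(
            title=f"Fixture revision {a} of {_latin_word(rng, 3).capitalize()}",
            authors=tuple(rng.sample(_AUTH_SYLLABLES, 2)),
            doi=f"10.9999/fixture.{spec.seed}.{a}",
            journal="Journal of Synthetic Taxonomy",
            work_id=OB[f"fixture/work/{a}"],
        )
        # number components deterministically under the article
        counter = itertools.count()
        for parent, child in root.walk():
            if child.id is None:
                child.id = OB[f"fixture/article/{a}/component/{next(counter)}"]
        build_article_graph(meta, root, graph=g)
        articles.append(root)
        treatments.extend(art_treatments)

    # --- names -----------------------------------------------------------
    names = [random_scientific_name(rng) for _ in range(spec.n_names)]
    name_iris = [OB[f"fixture/name/{i}"] for i in range(spec.n_names)]
    for iri, name in zip(name_iris, names):
        g.add((iri, RDF.type, T.SCIENTIFIC_NAME))
        g.add((iri, RDFS.label, Literal(format_name(name))))

    # --- name usages inside nomenclature sections ------------------------
    usages = []
    statuses = [s for s in StatusClass if s is not StatusClass.UNCLASSIFIED]
    patterns = status_patterns()
    for k, treatment in enumerate(treatments):
        if not name_iris:
            break
        nomen = treatment.children[0]
        for u in range(rng.randint(1, 3)):
            i = rng.randrange(len(name_iris))
            status = rng.choice(statuses) if rng.random() < 0.5 else None
            parse = TaxonomicNameUsageParse(
                name=names[i],
                status=status,
                status_verbatim=rng.choice(patterns[status]) if status else None,
            )
            usage = NameUsageNode(
                id=OB[f"fixture/usage/{k}/{u}"],
                parse=parse,
                mentioned_name_id=name_iris[i],
                container_id=nomen.id,
            )
            add_name_usage(g, usage)
            usages.append(usage)

    # --- name relations: replacement DAG + related edges -----------------
    for i, j in itertools.combinations(range(spec.n_names), 2):
        if rng.random() < spec.p_replacement:
            assert_name_relation(g, NameRelationEdge(
                name_iris[i], name_iris[j], "replacementName"))
            manifest["replacement_edges"].append([str(name_iris[i]), str(name_iris[j])])
        elif rng.random() < spec.p_related:
            assert_name_relation(g, NameRelationEdge(
                name_iris[i], name_iris[j], "relatedName"))
            manifest["related_edges"].append([str(name_iris[i]), str(name_iris[j])])

    # --- concepts with unique labels -------------------------------------
    concepts = []
    for c in range(spec.n_concepts):
        base = names[c % len(names)] if names else random_scientific_name(rng)
        label = TaxonomicConceptLabelParse(
            name=base,
            sec_reference=f"{rng.choice(_AUTH_SYLLABLES)}sen ({rng.randint(1900, 2020)}-{c})",
        )
        concept = TaxonomicConcept(
            id=OB[f"fixture/concept/{c}"],
            labels=(label,),
            scientific_name_ids=(name_iris[c % len(name_iris)],) if name_iris else (),
        )
        add_concept(g, concept)
        concepts.append(concept)
    for c, treatment in zip(concepts, treatments):
        realize_treatment(g, treatment.id, c.id)

    # --- parallel SKOS hierarchies ----------------------------------------
    for h in range(spec.n_hierarchies):
        edges = []
        for c in range(1, len(concepts)):
            if rng.random() < 0.7:
                parent = rng.randrange(c)
                assert_skos_relation(g, concepts[c].id, concepts[parent].id)
                edges.append([str(concepts[c].id), str(concepts[parent].id)])
        manifest["hierarchies"].append(edges)

    # --- RCC-5 statements from a concrete ground truth --------------------
    universe = range(6)
    ground_truth = {}
    for c in concepts:
        size = rng.randint(1, 5)
        ground_truth[c.id] = frozenset(rng.sample(list(universe), size))
    rcc5_statements = []
    s_counter = itertools.count()
    for a, b in itertools.combinations(concepts, 2):
        if rng.random() >= spec.rcc5_density:
            continue
        true_rel = relation_between(ground_truth[a.id], ground_truth[b.id])
        rels = {true_rel}
        if rng.random() < 0.3:  # disjunctive uncertainty, still satisfiable
            rels.add(rng.choice([r for r in RCC5 if r is not true_rel]))
        stmt = RCC5StatementSpec(
            id=OB[f"fixture/rcc5/{next(s_counter)}"],
            subject=a.id, object=b.id, relations=frozenset(rels),
            source="fixture ground truth",
        )
        assert_rcc5(g, stmt)
        rcc5_statements.append(stmt)

    manifest["entities"] = {
        "articles": [str(a.id) for a in articles],
        "treatments": [str(t.id) for t in treatments],
        "names": [str(n) for n in name_iris],
        "usages": [str(u.id) for u in usages],
        "concepts": [str(c.id) for c in concepts],
        "rcc5_statements": [str(s.id) for s in rcc5_statements],
    }
    manifest["rcc5_ground_truth"] = {
        str(c): sorted(members) for c, members in ground_truth.items()
    }

    _inject(g, spec, rng, manifest, treatments, name_iris, concepts)
    return g, manifest


def _inject(g, spec, rng, manifest, treatments, name_iris, concepts):
    """Apply the requested violations by raw triple surgery, recording each
    one in the manifest (kind, rule tripped, focus nodes)."""

    def record(kind, focus):
        manifest["injections"].append({
            "kind": kind,
            "rule": INJECTION_RULES[kind],
            "focus": [str(f) for f in focus],
        })

    for kind in spec.injections:
        if kind == "missing-label":
            node = OB[f"fixture/injected/unlabeled-concept"]
            g.add((node, RDF.type, T.TAXONOMIC_CONCEPT))
            record(kind, [node])
        elif kind == "shared-label":
            a, b = concepts[0], concepts[1]
            label_node = next(g.objects(a.id, T.TAXONOMIC_CONCEPT_LABEL_PROP))
            g.add((b.id, T.TAXONOMIC_CONCEPT_LABEL_PROP, label_node))
            record(kind, [a.id, b.id])
        elif kind == "scientific-name-domain":
            bad = OB["fixture/injected/not-a-concept"]
            g.add((bad, T.SCIENTIFIC_NAME_PROP, name_iris[0]))
            record(kind, [bad])
        elif kind == "usage-mentions-none":
            node = OB["fixture/injected/mute-usage"]
            g.add((node, RDF.type, T.TAXONOMIC_NAME_USAGE))
            record(kind, [node])
        elif kind == "containment-cycle":
            t = treatments[0]
            descendant = t.children[0]
            g.add((descendant.id, T.CONTAINS, t.id))
            record(kind, [t.id, descendant.id])
        elif kind == "bad-status":
            node = OB["fixture/injected/odd-status-usage"]
            g.add((node, RDF.type, T.TAXONOMIC_NAME_USAGE))
            g.add((node, T.MENTIONS, name_iris[0]))
            g.add((node, T.TAXONOMIC_STATUS_PROP, OB["NotAStatus"]))
            record(kind, [node])
        elif kind == "rcc5-malformed":
            node = OB["fixture/injected/hollow-rcc5"]
            g.add((node, RDF.type, T.RCC5_STATEMENT))
            g.add((node, T.HAS_SUBJECT_CONCEPT, concepts[0].id))
            record(kind, [node])
        elif kind == "realization-mismatch":
            nomen = treatments[0].children[0]
            g.add((nomen.id, T.FRBR.realizationOf, concepts[0].id))
            record(kind, [nomen.id])
        elif kind == "replacement-cycle":
            a, b = name_iris[0], name_iris[1]
            g.add((a, T.REPLACEMENT_NAME, b))
            g.add((b, T.REPLACEMENT_NAME, a))
            record(kind, [a, b])
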