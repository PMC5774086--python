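"""Taxonomic concepts: labels, SKOS hierarchy, RCC-5 statement, habitat.

The species-rank concept "Casuarinicola australis Taylor, 2010 sec.
Thorpe" is narrower than the genus-rank concept "Casuarinicola Taylor,
2010 sec. Taylor (2010)"; both mechanisms — SKOS broader/narrower and a
reified RCC-5 proper-part statement — are shown side by side.
"""

from rdflib import URIRef

from taxograph import terms as T
from taxograph.article import new_graph
from taxograph.concepts import (RCC5StatementSpec, TaxonomicConcept,
                                add_concept, assert_rcc5,
                                assert_skos_relation, attach_habitat)
from taxograph.names import parse_concept_label
from taxograph.vocabulary import RCC5

g = new_graph()
species = TaxonomicConcept(
    id=T.OB["concept/australis-sec-thorpe"],
    labels=(parse_concept_label(
        "Casuarinicola australis Taylor, 2010 sec. Thorpe"),),
)
genus = TaxonomicConcept(
    id=T.OB["concept/casuarinicola-sec-taylor"],
    labels=(parse_concept_label("Casuarinicola Taylor, 2010 sec. Taylor (2010)"),),
)
add_concept(g, species)
add_concept(g, genus)

assert_skos_relation(g, narrower=species.id, broader=genus.id)
assert_rcc5(g, RCC5StatementSpec(
    id=T.OB["statement/1"],
    subject=species.id, object=genus.id,
    relations=frozenset({RCC5.PP}),
    source="Thorpe (2013)",
))

# habitat shortcut to an external environment-ontology term
attach_habitat(g, species.id,
               URIRef("http://purl.obolibrary.org/obo/RO_0002303"))

print(f"graph: {len(g)} triples")
print("species concept label:", species.labels[0].verbatim)
print("narrower-than genus:", (species.id, T.SKOS.broader, genus.id) in g)
print("RCC-5 statement relations:",
      [str(o).rsplit('/', 1)[-1] for o in g.objects(T.OB["statement/1"], T.HAS_RELATION)])

# Every label identifies exactly one concept; re-adding a concept with the
# same label raises LabelUniquenessViolation.
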