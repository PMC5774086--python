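"""Emit the core ontology and the two controlled vocabularies.

The status vocabulary has exactly 8 concepts (the recurring kinds of
nomenclatural act trailing a name in print); the RCC-5 vocabulary has the
5 base relations used to align taxonomic concepts.
"""

from rdflib import RDF, SKOS

from taxograph import terms as T
from taxograph.vocabulary import (classify_status, emit_core_ontology,
                                  rcc5_vocabulary, status_vocabulary)

onto = emit_core_ontology()
statuses = status_vocabulary()
rcc5 = rcc5_vocabulary()

print(f"core ontology:    {len(onto)} triples")
print(f"status scheme:    {len(set(statuses.subjects(SKOS.inScheme, T.STATUS_SCHEME)))} concepts")
print(f"RCC-5 scheme:     {len(set(rcc5.subjects(RDF.type, T.RCC5_RELATION)))} relations")

for abbrev in ("sp. n.", "comb. n.", "Sp. Nov.", "something odd"):
    print(f"classify_status({abbrev!r}) -> {classify_status(abbrev).value}")

# The counts are the vocabulary cardinalities; classification is
# normalization-insensitive and falls back to Unclassified.
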