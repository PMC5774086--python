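# Methods

This note documents the model implemented by `taxograph`, its assumptions,
the parameters that matter, and the design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The modeled domain

The package represents the *process* of taxonomy, not a fixed
classification. Its unit of meaning is the **taxonomic concept**: the
falsifiable circumscription hypothesis an author publishes for a taxon.
Concepts are identified by **taxonomic concept labels** (`name sec.
reference`); Linnaean names are deliberately *not* identifiers — the
relationship between concepts and plain names is many-to-many, while the
relationship between concepts and labels is one-to-many with every label
naming exactly one concept. This is encoded as a minimum-cardinality-1
restriction plus an inverse-functional label property in the emitted
ontology, and enforced operationally by `add_concept` and the validator.

Articles follow the FRBR split: one *work* (abstract research paper) per
*expression* (the taxonomic article, version of record). Document
structure is a tree of typed components joined by `contains`, declared
transitive and a subproperty of the external part-whole containment
property; the transitive closure is computed on demand (networkx) rather
than materialized, so asserted and inferred triples stay distinct (an
opt-in `materialize` flag exists). Component order is preserved with an
integer `position` annotation, since document order matters to consumers
but RDF triples are unordered.

External alignments: taxonomic articles ⊑ FaBiO journal article; section
classes ⊑ DEO discourse element; concepts ⊑ SKOS concept, ⊑ FRBR work,
⊑ operational taxonomic unit, and ≡ the Darwin Core taxon class; the
scientific-name property parallels the Darwin Core IRI term but with
declared domain (concept) and range (scientific name). The habitat
shortcut is a property minted as a subproperty of the OBO *has habitat*
relation; it simply passes an external environment-ontology IRI through.

## Controlled vocabularies

**Taxonomic statuses.** Eight classes cover the recurring statuses of
taxonomic journals: TaxonomicUncertainty, TaxonDiscovery, ReplacementName,
UnavailableName, AvailableName, TypeSpecimenDesignation,
TypeSpeciesDesignation, NewOccurrenceRecord; a ninth member,
`Unclassified`, makes classification total but is not part of the
vocabulary. Matching normalizes case, collapses whitespace and ignores a
trailing period. The shipped abbreviation map holds each class's exemplar
plus common orthographic variants; the replacement-name class carries the
three patterns it subsumes in practice (`comb. n.`, `nomen novum`,
`syn. nov.`). The map is extensible at run time from YAML
(`load_status_patterns`) because the long tail of Latin abbreviations is
open-ended.

**RCC-5.** The five base relations over non-empty sets, with mnemonic
names from the standard calculus (EQ, PP, PPi, PO, DR) and converse links
encoded in the vocabulary graph (converse is an involution; PP ↔ PPi).

## Name grammar

`Genus [epithet] [marker epithet] [authorship [,] year | (authorship, year)]`,
with markers `var. subsp. ssp. subvar. f. forma`. Authorship is kept
opaque (no author splitting — out of scope), NFC normalization is applied
before tokenizing, and `sec.` is matched case-sensitively as an exact
token; a bare-name parse that encounters `sec.` fails loudly rather than
absorbing it into authorship. One representational addition:
`year_comma` records whether the printed form separates authorship and
year with a comma (`Taylor, 2010` vs `Deltschev 2016`), because
`format(parse(s))` is required to reproduce the printed form and both
conventions occur. Known ambiguity: after a uninomial, a lowercase-leading
authorship particle (e.g. `van ...`) is indistinguishable from an epithet;
the parser prefers the epithet reading, and generated fixtures use
uppercase-leading authorships as in citation practice. Status splitting in
a name usage probes a comma-delimited tail first, then the last 1–3
whitespace tokens, and accepts only tails the status classifier
recognizes — so year or authorship tokens can never be consumed as a
status.

## Name resolution

Replacement-name chains are followed over the directed `replacementName`
graph; every reachable terminal (out-degree 0) is returned, with one
shortest path per terminal. Branching chains return *all* terminals — the
model imposes no year-based precedence, leaving arbitration to the user.
Cycles among reachable names are detected (strongly connected components)
and reported in the result object, never silently broken. Neighborhood
queries treat `relatedName ∪ replacementName` as undirected with an
explicit depth; `relatedName` is symmetric but deliberately not
transitive, and assumed irreflexive.

## RCC-5 reasoning

The composition table is authored from the set semantics (e.g. PP∘PP =
{PP}; PP∘DR = {DR}; DR∘DR = all five) and cross-checked in tests against
an independent oracle that enumerates all triples of non-empty subsets of
a 4-element universe — 4 elements suffice to realize every consistent
RCC-5 configuration, the worst case being two partially overlapping sets
both disjoint from a third. Path consistency intersects each edge with
the union of compositions through every third node until fixpoint;
refinement is monotone, so the fixpoint is unique and order-independent.
The algorithm is sound (an emptied edge really is unsatisfiable — checked
against the oracle) but incomplete in general; full reasoning over large
alignment problems is explicitly out of scope, answer-set-programming
tools existing for that purpose. The satisfiability oracle uses
backtracking (assign nodes in order, prune on any violated edge) rather
than raw cross-product enumeration, with the same verdicts; it refuses
more than 6 nodes or a universe beyond 6 elements, which is where
exhaustive search stops being desk-scale. Graph-level checking extracts
the network from reified statements, intersecting multiple statements
about the same pair; malformed statements become warnings and are
excluded. SKOS `broader` links can optionally be imported as {PP} edges
(`import_skos=True`, default off): the two alignment mechanisms are
presented as parallel, not equivalent.

## Validation

Closed-world rule checks, not OWL inference — open-world semantics would
merge two concepts sharing a label rather than flag them, and the intent
of labels is to be unique identifiers. Eight rules (see the module
docstring) cover label cardinality and uniqueness, scientific-name
domain/range, mention multiplicity (zero targets is an error; several, a
warning, since the model only demands that a usage mention *a* name),
containment acyclicity, status vocabulary membership, RCC-5 statement
well-formedness, and treatment-realization typing (articles realizing
works are exempt — only component→concept realizations are constrained).
Labels are compared as whitespace-normalized strings, recorded in the
report metadata; reports are sorted by rule then focus node, so a fixed
graph yields a byte-identical report.

## Synthetic fixtures

The generator emulates the *shapes* of taxonomic literature: articles
whose treatments each contain a nomenclature section (with heading and
optional citation list) plus optional materials-examined / description /
biology subsections; pseudo-Latin names built from syllable templates so
the parser round-trips on realistic forms; statuses sampled from the
vocabulary; replacement edges drawn only forward along a fixed name
ordering (acyclic by construction); concepts with unique labels arranged
in `n_hierarchies` parallel SKOS hierarchies; and RCC-5 statements read
off a concrete random set assignment over a 6-element universe, which
makes clean fixtures satisfiable by construction, with occasional extra
disjuncts that preserve satisfiability. Defaults (2 articles × 3
treatments, 20 names, replacement probability 0.15, related 0.10, 8
concepts, RCC-5 density 0.3) keep a fixture in the few-hundred-triple
range — large enough to exercise every code path, small enough that the
full suite runs in seconds. The generator is a pure function of its spec:
IRIs come from deterministic counters, randomness from one seeded
generator, and the same seed yields byte-identical Turtle.

What fixtures do **not** emulate: the statistical texture of real corpora
(journal sizes, rank distributions, real Latin, OCR noise, editorial
inconsistency). Passing tests therefore demonstrate correctness of the
graph semantics, parsers and reasoners on well-formed and
deliberately-broken input shapes — not extraction performance on real
articles, which is outside this package's scope altogether (no text
mining, no occurrence modeling, no trait ontologies).

## Problem sizes and numerical choices

The oracle-agreement suites run at sizes where the independent oracles
are exact and fast: 200 random trees (≤ 25 components) for containment
closure vs. DFS ancestor enumeration; 200 random DAGs (≤ 12 names) for
resolution vs. reachability; all 25 composition pairs vs. enumeration
over a 4-element universe; all 125 singleton 3-node networks plus 200
random 5-node networks for path-consistency soundness; 5 fixture seeds ×
8 injection kinds for validator recall. There are no tolerances anywhere:
every check is exact set/graph equality or an exact count, and graph
comparison uses blank-node-aware RDF isomorphism.

## Known limitations

* The name grammar covers uninomials through trinomials with a single
  authorship block; hybrid formulas, multi-rank botanical strings and
  code-specific validity rules are out of scope.
* Path consistency is incomplete for RCC-5 in general; the package offers
  it as a sound desk-scale check, with the exhaustive oracle limited to
  6 nodes.
* The validator checks the model's own contracts only; it does not
  entail or check external-ontology semantics.
* Concept labels compare by normalized string, not by node identity, so
  typographically distinct but semantically identical references count as
  different labels.
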