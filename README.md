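# taxograph

RDF toolkit for the semantics of taxonomic publishing: build, serialize,
validate and reason over graphs of **taxonomic articles**, **scientific
names** and **taxonomic concepts**.

## The problem

Biological taxonomy advances by publication: a taxonomist examines
specimens, forms a hypothesis about a taxon — a *taxonomic concept* — and
publishes it in an article whose *treatment* section carries the
nomenclature, the examined material and the description. Linnaean names
alone cannot identify these hypotheses: the same name is reused across
conflicting circumscriptions, and names are replaced over time (new
combinations, nomina nova, junior synonyms). `taxograph` is aimed at
biodiversity informaticians who need to represent this process — not any
single fixed classification — as a linked-data graph, with multiple
simultaneous hierarchies of concepts and explicit, checkable relations
between them.

## The model

* **Articles** are modeled at two bibliographic levels (FRBR): the abstract
  *work* and the *expression* of record, a taxonomic article (subclass of
  journal article). Content is a tree of typed components — `Treatment`,
  `NomenclatureSection`, `MaterialsExamined`, `TaxonomicKey`,
  `TaxonomicChecklist`, … — linked by the transitive property `contains`.
* **Name usages** (`TaxonomicNameUsage`) are mention regions of a document:
  a section *contains* the usage, the usage *mentions* a taxonomic name,
  and may carry one of the **8 taxonomic statuses** of the controlled
  vocabulary (`sp. n.` → TaxonDiscovery, `comb. n.` → ReplacementName,
  `incertae sedis` → TaxonomicUncertainty, …).
* **Name patterns**: `replacementName` (directed; chains resolve to the
  currently used name) and `relatedName` (symmetric, no preference).
* **Taxonomic concepts** are SKOS concepts, FRBR works (realized by
  treatments), Darwin Core taxa and operational taxonomic units at once.
  Each carries ≥ 1 *taxonomic concept label* — `name sec. reference` — and
  every label identifies exactly one concept (the label property is
  inverse functional).
* **Concept alignment** is either simple SKOS `broader`/`narrower` or a
  reified `RCC5Statement` holding a disjunction over the five base
  relations of the Region Connection Calculus RCC-5 — EQ (equal), PP
  (proper part), PPi (has proper part), PO (partial overlap), DR
  (disjoint) — interpreting concepts as non-empty sets.

A small reasoner performs composition-based **path consistency** over
RCC-5 constraint networks (`R(i,j) ← R(i,j) ∩ ⋃ₖ R(i,k)∘R(k,j)` to
fixpoint): sound, incomplete, desk-scale; an exhaustive finite-model
oracle (backtracking over non-empty subsets of a ≤ 6-element universe)
verifies it. A closed-world **validator** checks the graph-level contracts
(label cardinality and uniqueness, domain/range, acyclic containment,
vocabulary membership, statement well-formedness), and a seeded
**fixture generator** produces realistic synthetic graphs, clean or with
manifest-tracked injected violations.

## Worked example

From `examples/04_concepts_alignment.py` — the species-rank concept
*Casuarinicola australis* Taylor, 2010 sec. Thorpe is a narrower concept
than the genus-rank *Casuarinicola* Taylor, 2010 sec. Taylor (2010),
expressed both ways:

```text
graph: 28 triples
species concept label: Casuarinicola australis Taylor, 2010 sec. Thorpe
narrower-than genus: True
RCC-5 statement relations: ['properPart']
```

and from `examples/05_rcc5_reasoning.py`, the reasoner at work:

```text
compose(PP, PP) = ['PP']
A-C refined to: ['PP']
contradictory network: inconsistent
oracle agrees (unsatisfiable): True
```

The first two lines say that proper-parthood composes transitively, so a
chain A ⊂ B ⊂ C forces A ⊂ C; the last two show a network that asserts
A ⊂ B ⊂ C yet A disjoint from C being rejected by path consistency, in
agreement with the exhaustive model search.

Other examples cover vocabulary emission (`01`), name/usage/label parsing
(`02`, e.g. `Heser stoevi Deltschev 2016, sp. n.` → genus `Heser`, year
2016, status TaxonDiscovery), article building with containment closure
(`03`) and fixture generation plus validation (`06`).

A thin CLI wraps the same calls:

```bash
taxograph parse-name "Heser stoevi Deltschev 2016, sp. n."
taxograph emit statuses --format turtle
taxograph fixtures --seed 4 --out /tmp/fx --inject shared-label
taxograph validate /tmp/fx/fixture.ttl      # exit 1, label-unique errors
taxograph rcc5-check /tmp/fx/fixture.ttl --report json
```

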