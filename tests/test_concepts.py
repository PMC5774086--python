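"""Taxonomic concepts, name relations, SKOS/RCC-5 alignment, treatments."""

import itertools
import random

import networkx as nx
import pytest
from rdflib import RDF, SKOS, URIRef

from taxograph import terms as T
from taxograph.article import (ArticleMetadata, DocumentComponent, IriMinter,
                               build_article_graph, new_graph)
from taxograph.concepts import (CardinalityViolation, InvalidEdgeError,
                                LabelUniquenessViolation, NameRelationEdge,
                                RCC5StatementSpec, TaxonomicConcept,
                                add_concept, assert_name_relation, assert_rcc5,
                                assert_skos_relation, attach_habitat,
                                realize_treatment, related_name_neighborhood,
                                resolve_current_names)
from taxograph.names import parse_concept_label
from taxograph.vocabulary import RCC5

OB = T.OB


def concept(i, label_text):
    return TaxonomicConcept(
        id=OB[f"c/{i}"],
        labels=(parse_concept_label(label_text),),
    )


@pytest.fixture()
def g():
    return new_graph()


class TestAddConcept:
    def test_concept_with_label_accepted_and_four_ways_typed(self, g):
        c = concept(1, "Casuarinicola australis Taylor, 2010 sec. Thorpe")
        add_concept(g, c)
        for cls in (T.TAXONOMIC_CONCEPT, SKOS.Concept, T.FRBR.Work, T.DWC.Taxon):
            assert (c.id, RDF.type, cls) in g

    def test_label_reuse_by_second_concept_rejected(self, g):
        add_concept(g, concept(1, "Casuarinicola australis Taylor, 2010 sec. Thorpe"))
        with pytest.raises(LabelUniquenessViolation):
            add_concept(g, concept(2, "Casuarinicola australis Taylor, 2010 sec. Thorpe"))

    def test_concept_with_two_distinct_labels_accepted(self, g):
        c = TaxonomicConcept(
            id=OB["c/1"],
            labels=(
                parse_concept_label("Aus bus sec. Smith (1990)"),
                parse_concept_label("Aus bus sec. Jones (2001)"),
            ),
        )
        add_concept(g, c)
        assert len(list(g.objects(c.id, T.TAXONOMIC_CONCEPT_LABEL_PROP))) == 2

    def test_zero_labels_is_a_cardinality_violation(self):
        with pytest.raises(CardinalityViolation):
            TaxonomicConcept(id=OB["c/1"], labels=())


def name_graph(g, n):
    iris = [OB[f"name/{i}"] for i in range(n)]
    for iri in iris:
        g.add((iri, RDF.type, T.SCIENTIFIC_NAME))
    return iris


class TestNameRelations:
    def test_related_name_asserted_symmetrically(self, g):
        a, b = name_graph(g, 2)
        assert_name_relation(g, NameRelationEdge(a, b, "relatedName"))
        assert (a, T.RELATED_NAME, b) in g and (b, T.RELATED_NAME, a) in g

    def test_replacement_is_directed(self, g):
        a, b = name_graph(g, 2)
        assert_name_relation(g, NameRelationEdge(a, b, "replacementName"))
        assert (a, T.REPLACEMENT_NAME, b) in g
        assert (b, T.REPLACEMENT_NAME, a) not in g

    def test_self_loop_rejected(self, g):
        (a,) = name_graph(g, 1)
        with pytest.raises(InvalidEdgeError):
            NameRelationEdge(a, a, "replacementName")

    def test_unknown_name_node_rejected(self, g):
        (a,) = name_graph(g, 1)
        with pytest.raises(InvalidEdgeError):
            assert_name_relation(
                g, NameRelationEdge(a, OB["name/ghost"], "relatedName"))


class TestResolveCurrentNames:
    def test_chain_resolves_to_final_name(self, g):
        a, b, c = name_graph(g, 3)
        assert_name_relation(g, NameRelationEdge(a, b, "replacementName"))
        assert_name_relation(g, NameRelationEdge(b, c, "replacementName"))
        report = resolve_current_names(g, a)
        assert report.terminals == {c}
        assert report.paths[c] == (a, b, c)
        assert not report.has_cycle

    def test_isolated_name_resolves_to_itself(self, g):
        (a,) = name_graph(g, 1)
        report = resolve_current_names(g, a)
        assert report.terminals == {a}

    def test_branching_returns_all_terminals(self, g):
        a, b, c = name_graph(g, 3)
        assert_name_relation(g, NameRelationEdge(a, b, "replacementName"))
        assert_name_relation(g, NameRelationEdge(a, c, "replacementName"))
        assert resolve_current_names(g, a).terminals == {b, c}

    def test_injected_two_cycle_reported_not_broken(self, g):
        a, b = name_graph(g, 2)
        g.add((a, T.REPLACEMENT_NAME, b))
        g.add((b, T.REPLACEMENT_NAME, a))
        report = resolve_current_names(g, a)
        assert report.has_cycle
        assert {a, b} in [set(cyc) for cyc in report.cycles]

    def test_resolution_is_idempotent_on_terminals(self, g):
        iris = name_graph(g, 10)
        rng = random.Random(1)
        for i, j in itertools.combinations(range(10), 2):
            if rng.random() < 0.3:
                assert_name_relation(
                    g, NameRelationEdge(iris[i], iris[j], "replacementName"))
        for start in iris:
            for t in resolve_current_names(g, start).terminals:
                assert resolve_current_names(g, t).terminals == {t}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reachability_oracle_on_random_dags(self, g, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 15)
        iris = name_graph(g, n)
        dg = nx.DiGraph()
        dg.add_nodes_from(iris)
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.25:
                assert_name_relation(
                    g, NameRelationEdge(iris[i], iris[j], "replacementName"))
                dg.add_edge(iris[i], iris[j])
        for start in iris:
            # brute-force: enumerate reachable, keep sinks
            reachable = {start} | nx.descendants(dg, start)
            expected = {x for x in reachable if dg.out_degree(x) == 0}
            assert resolve_current_names(g, start).terminals == expected


class TestRelatedNeighborhood:
    def test_symmetric_pair_depth_one(self, g):
        a, b = name_graph(g, 2)
        assert_name_relation(g, NameRelationEdge(a, b, "relatedName"))
        assert related_name_neighborhood(g, a, 1) == {b}
        assert related_name_neighborhood(g, b, 1) == {a}

    def test_isolated_name_has_empty_neighborhood(self, g):
        (a,) = name_graph(g, 1)
        assert related_name_neighborhood(g, a, 3) == frozenset()

    def test_depth_below_one_rejected(self, g):
        (a,) = name_graph(g, 1)
        with pytest.raises(InvalidEdgeError):
            related_name_neighborhood(g, a, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_large_depth_equals_connected_component(self, g, seed):
        rng = random.Random(seed)
        n = 12
        iris = name_graph(g, n)
        ug = nx.Graph()
        ug.add_nodes_from(iris)
        for i, j in itertools.combinations(range(n), 2):
            r = rng.random()
            if r < 0.12:
                assert_name_relation(
                    g, NameRelationEdge(iris[i], iris[j], "relatedName"))
                ug.add_edge(iris[i], iris[j])
            elif r < 0.2:
                assert_name_relation(
                    g, NameRelationEdge(iris[i], iris[j], "replacementName"))
                ug.add_edge(iris[i], iris[j])
        for start in iris:
            expected = nx.node_connected_component(ug, start) - {start}
            assert related_name_neighborhood(g, start, n) == expected

    def test_depth_one_membership_is_symmetric(self, g):
        iris = name_graph(g, 8)
        rng = random.Random(4)
        for i, j in itertools.combinations(range(8), 2):
            if rng.random() < 0.3:
                kind = rng.choice(["relatedName", "replacementName"])
                assert_name_relation(g, NameRelationEdge(iris[i], iris[j], kind))
        for a in iris:
            for b in iris:
                if a == b:
                    continue
                assert (b in related_name_neighborhood(g, a, 1)) == (
                    a in related_name_neighborhood(g, b, 1))


class TestSkosRelations:
    def test_narrower_broader_pair_asserted(self, g):
        c1 = concept(1, "Casuarinicola australis Taylor, 2010 sec. Thorpe")
        c2 = concept(2, "Casuarinicola Taylor, 2010 sec. Taylor (2010)")
        add_concept(g, c1)
        add_concept(g, c2)
        assert_skos_relation(g, c1.id, c2.id)
        assert (c1.id, SKOS.broader, c2.id) in g
        assert (c2.id, SKOS.narrower, c1.id) in g

    def test_two_parallel_hierarchies_coexist(self, g):
        cs = [concept(i, f"Aus bus sec. Ref{i} (200{i})") for i in range(3)]
        for c in cs:
            add_concept(g, c)
        assert_skos_relation(g, cs[0].id, cs[1].id)
        before = set(g)
        assert_skos_relation(g, cs[0].id, cs[2].id)  # second classification
        assert before <= set(g)
        assert len(list(g.objects(cs[0].id, SKOS.broader))) == 2

    def test_self_relation_rejected(self, g):
        c = concept(1, "Aus bus sec. Smith")
        add_concept(g, c)
        with pytest.raises(InvalidEdgeError):
            assert_skos_relation(g, c.id, c.id)


class TestRCC5Statements:
    def test_singleton_statement_reified(self, g):
        c1 = concept(1, "Casuarinicola australis Taylor, 2010 sec. Thorpe")
        c2 = concept(2, "Casuarinicola Taylor, 2010 sec. Taylor (2010)")
        add_concept(g, c1)
        add_concept(g, c2)
        stmt = RCC5StatementSpec(id=OB["s/1"], subject=c1.id, object=c2.id,
                                 relations=frozenset({RCC5.PP}))
        assert_rcc5(g, stmt)
        assert (stmt.id, RDF.type, T.RCC5_STATEMENT) in g
        assert list(g.objects(stmt.id, T.HAS_RELATION)) == [RCC5.PP.iri]

    def test_disjunction_has_one_link_per_relation(self, g):
        stmt = RCC5StatementSpec(id=OB["s/1"], subject=OB["c/1"],
                                 object=OB["c/2"],
                                 relations=frozenset({RCC5.PP, RCC5.EQ}))
        assert_rcc5(g, stmt)
        assert len(list(g.objects(stmt.id, T.HAS_RELATION))) == 2

    def test_empty_relation_set_rejected(self):
        with pytest.raises(InvalidEdgeError):
            RCC5StatementSpec(id=OB["s/1"], subject=OB["c/1"],
                              object=OB["c/2"], relations=frozenset())

    def test_subject_equal_object_rejected(self):
        with pytest.raises(InvalidEdgeError):
            RCC5StatementSpec(id=OB["s/1"], subject=OB["c/1"],
                              object=OB["c/1"],
                              relations=frozenset({RCC5.EQ}))


class TestTreatmentsAndHabitat:
    def _article(self, g):
        nomen = DocumentComponent("NomenclatureSection")
        treatment = DocumentComponent("Treatment", children=[nomen])
        root = DocumentComponent("TaxonomicArticle", children=[treatment])
        build_article_graph(ArticleMetadata(title="t"), root, graph=g,
                            minter=IriMinter(seed=8))
        return treatment, nomen

    def test_treatment_realizes_concept(self, g):
        treatment, _ = self._article(g)
        c = concept(1, "Aus bus sec. Smith")
        add_concept(g, c)
        realize_treatment(g, treatment.id, c.id)
        assert (treatment.id, T.FRBR.realizationOf, c.id) in g

    def test_non_treatment_section_cannot_realize(self, g):
        _, nomen = self._article(g)
        c = concept(1, "Aus bus sec. Smith")
        add_concept(g, c)
        with pytest.raises(InvalidEdgeError):
            realize_treatment(g, nomen.id, c.id)

    def test_two_treatments_may_realize_one_concept(self, g):
        t1, _ = self._article(g)
        t2 = DocumentComponent("Treatment", id=OB["t/extra"])
        g.add((t2.id, RDF.type, T.TREATMENT))
        c = concept(1, "Aus bus sec. Smith")
        add_concept(g, c)
        realize_treatment(g, t1.id, c.id)
        realize_treatment(g, t2.id, c.id)
        assert len(list(g.subjects(T.FRBR.realizationOf, c.id))) == 2

    def test_habitat_link_and_idempotence(self, g):
        c = concept(1, "Casuarinicola australis Taylor, 2010 sec. Thorpe")
        add_concept(g, c)
        habitat = URIRef("http://purl.obolibrary.org/obo/RO_0002303")
        attach_habitat(g, c.id, habitat)
        before = len(g)
        attach_habitat(g, c.id, habitat)
        assert len(g) == before
        assert (c.id, T.HABITAT_PROP, habitat) in g

    def test_malformed_habitat_iri_rejected(self, g):
        c = concept(1, "Aus bus sec. Smith")
        add_concept(g, c)
        with pytest.raises(InvalidEdgeError):
            attach_habitat(g, c.id, "not an iri")
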