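"""Article graphs: component trees, containment closure, serialization."""

import random

import pytest
from rdflib import RDF, URIRef

from taxograph import terms as T
from taxograph.article import (ArticleMetadata, DocumentComponent, IriMinter,
                               NameUsageNode, ReferenceError_,
                               StructuralError, add_name_usage,
                               build_article_graph, contains_closure,
                               graphs_isomorphic, parse_graph, roundtrip,
                               serialize_graph)
from taxograph.names import parse_taxonomic_name_usage


def small_article():
    nomen = DocumentComponent("NomenclatureSection")
    treatment = DocumentComponent("Treatment", children=[nomen])
    root = DocumentComponent("TaxonomicArticle", children=[treatment])
    meta = ArticleMetadata(title="A revision", authors=("A. Author",),
                           doi="10.1/x")
    g = build_article_graph(meta, root, minter=IriMinter(seed=1))
    return g, root, treatment, nomen


class TestBuildArticleGraph:
    def test_treatment_chain_yields_two_contains_triples(self):
        g, root, treatment, nomen = small_article()
        edges = list(g.subject_objects(T.CONTAINS))
        assert len(edges) == 2
        assert (root.id, T.CONTAINS, treatment.id) in g
        assert (treatment.id, T.CONTAINS, nomen.id) in g

    def test_work_and_expression_distinct_and_linked(self):
        g, root, *_ = small_article()
        works = list(g.subjects(RDF.type, T.FABIO.ResearchPaper))
        assert len(works) == 1 and works[0] != root.id
        assert (root.id, T.FRBR.realizationOf, works[0]) in g
        assert (root.id, RDF.type, T.TAXONOMIC_ARTICLE) in g

    def test_childless_article_has_no_contains(self):
        root = DocumentComponent("TaxonomicArticle")
        g = build_article_graph(ArticleMetadata(title="t"), root,
                                minter=IriMinter(seed=2))
        assert list(g.subject_objects(T.CONTAINS)) == []

    def test_n_components_give_n_minus_one_edges(self):
        rng = random.Random(5)
        root = random_tree(rng, 30)
        g = build_article_graph(ArticleMetadata(title="t"), root,
                                minter=IriMinter(seed=3))
        n = 1 + sum(1 for _ in root.walk())
        assert len(list(g.subject_objects(T.CONTAINS))) == n - 1

    def test_root_must_be_article(self):
        with pytest.raises(StructuralError):
            build_article_graph(ArticleMetadata(title="t"),
                                DocumentComponent("Treatment"))

    def test_cyclic_component_structure_rejected(self):
        a = DocumentComponent("Treatment")
        b = DocumentComponent("NomenclatureSection", children=[a])
        a.children.append(b)
        root = DocumentComponent("TaxonomicArticle", children=[a])
        with pytest.raises(StructuralError):
            build_article_graph(ArticleMetadata(title="t"), root)

    def test_unknown_kind_rejected(self):
        with pytest.raises(StructuralError):
            DocumentComponent("Acknowledgements")


class TestNameUsage:
    def test_usage_contained_mentioning_with_status(self):
        g, _, treatment, nomen = small_article()
        usage = NameUsageNode(
            id=URIRef("http://openbiodiv.net/u1"),
            parse=parse_taxonomic_name_usage("Heser stoevi Deltschev 2016, sp. n."),
            mentioned_name_id=URIRef("http://openbiodiv.net/n1"),
            container_id=treatment.id,
        )
        add_name_usage(g, usage)
        assert (treatment.id, T.CONTAINS, usage.id) in g
        assert (usage.id, T.MENTIONS, usage.mentioned_name_id) in g
        from taxograph.vocabulary import StatusClass
        assert (usage.id, T.TAXONOMIC_STATUS_PROP,
                StatusClass.TAXON_DISCOVERY.iri) in g

    def test_usage_without_status_adds_no_status_triple(self):
        g, _, treatment, _ = small_article()
        usage = NameUsageNode(
            id=URIRef("http://openbiodiv.net/u2"),
            parse=parse_taxonomic_name_usage("Heser stoevi Deltschev 2016"),
            mentioned_name_id=URIRef("http://openbiodiv.net/n1"),
            container_id=treatment.id,
        )
        add_name_usage(g, usage)
        assert list(g.objects(usage.id, T.TAXONOMIC_STATUS_PROP)) == []

    def test_two_usages_share_one_name_node(self):
        g, _, treatment, nomen = small_article()
        name = URIRef("http://openbiodiv.net/n1")
        for i, container in enumerate((treatment.id, nomen.id)):
            add_name_usage(g, NameUsageNode(
                id=URIRef(f"http://openbiodiv.net/u{i}"),
                parse=parse_taxonomic_name_usage("Aus bus Smith 1900"),
                mentioned_name_id=name,
                container_id=container,
            ))
        usages = set(g.subjects(RDF.type, T.TAXONOMIC_NAME_USAGE))
        names = set(g.subjects(RDF.type, T.SCIENTIFIC_NAME))
        assert len(usages) == 2 and names == {name}

    def test_unknown_container_rejected(self):
        g, *_ = small_article()
        with pytest.raises(ReferenceError_):
            add_name_usage(g, NameUsageNode(
                id=URIRef("http://openbiodiv.net/u9"),
                parse=parse_taxonomic_name_usage("Aus bus"),
                mentioned_name_id=URIRef("http://openbiodiv.net/n1"),
                container_id=URIRef("http://openbiodiv.net/nowhere"),
            ))


def random_tree(rng: random.Random, n: int) -> DocumentComponent:
    """Random component tree with n non-root nodes (uniform random parent)."""
    kinds = ["Treatment", "NomenclatureSection", "MaterialsExamined",
             "DescriptionSection", "BiologySection", "GenericDiscourseElement"]
    root = DocumentComponent("TaxonomicArticle")
    nodes = [root]
    for _ in range(n):
        child = DocumentComponent(rng.choice(kinds))
        rng.choice(nodes).children.append(child)
        nodes.append(child)
    return root


def closure_by_dfs(root: DocumentComponent) -> set:
    """Brute-force ancestor enumeration: independent closure oracle."""
    pairs = set()

    def rec(node, ancestors):
        for anc in ancestors:
            pairs.add((anc.id, node.id))
        for child in node.children:
            rec(child, ancestors + [node])

    rec(root, [])
    return pairs


class TestContainsClosure:
    def test_article_treatment_nomenclature_chain(self):
        g, root, treatment, nomen = small_article()
        closure = contains_closure(g)
        assert (root.id, nomen.id) in closure
        assert len(closure) == 3

    def test_single_node_closure_empty(self):
        root = DocumentComponent("TaxonomicArticle")
        g = build_article_graph(ArticleMetadata(title="t"), root,
                                minter=IriMinter(seed=4))
        assert contains_closure(g) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dfs_oracle_on_random_trees(self, seed):
        rng = random.Random(seed)
        root = random_tree(rng, rng.randint(2, 40))
        g = build_article_graph(ArticleMetadata(title="t"), root,
                                minter=IriMinter(seed=seed))
        assert contains_closure(g) == closure_by_dfs(root)

    def test_closure_is_idempotent_and_superset_of_asserted(self):
        rng = random.Random(99)
        root = random_tree(rng, 25)
        g = build_article_graph(ArticleMetadata(title="t"), root,
                                minter=IriMinter(seed=99))
        asserted = set(g.subject_objects(T.CONTAINS))
        closure = contains_closure(g, materialize=True)
        assert asserted <= closure
        assert contains_closure(g) == closure

    def test_materialize_off_keeps_graph_unchanged(self):
        g, *_ = small_article()
        before = len(g)
        contains_closure(g)
        assert len(g) == before


class TestRoundtrip:
    @pytest.mark.parametrize("fmt", ["turtle", "rdfxml"])
    def test_roundtrip_isomorphic(self, fmt):
        g, *_ = small_article()
        assert graphs_isomorphic(g, roundtrip(g, fmt))

    def test_truncated_turtle_raises(self, tmp_path):
        g, *_ = small_article()
        data = serialize_graph(g, fmt="turtle")
        bad = tmp_path / "bad.ttl"
        bad.write_text(data[: len(data) // 2].rsplit("\n", 1)[0] + " @@@")
        with pytest.raises(Exception):
            parse_graph(str(bad), fmt="turtle")

    def test_fixture_graph_roundtrips(self, clean_graph):
        for fmt in ("turtle", "rdfxml"):
            assert graphs_isomorphic(clean_graph, roundtrip(clean_graph, fmt))
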