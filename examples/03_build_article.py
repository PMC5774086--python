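"""Build an article graph: component tree, name usage, containment closure.

The article expression is linked to its abstract work; sections are typed
components linked by the transitive `contains`; the usage is a mention
node inside its section.
"""

from taxograph.article import (ArticleMetadata, DocumentComponent, IriMinter,
                               NameUsageNode, add_name_usage,
                               build_article_graph, contains_closure)
from taxograph.names import parse_taxonomic_name_usage

nomenclature = DocumentComponent("NomenclatureSection")
treatment = DocumentComponent("Treatment", children=[nomenclature])
root = DocumentComponent("TaxonomicArticle", children=[treatment])

minter = IriMinter(seed=7)
graph = build_article_graph(
    ArticleMetadata(
        title="A new ground spider from the Balkans",
        authors=("C. Deltschev",),
        doi="10.9999/example.1",
    ),
    root,
    minter=minter,
)

usage = NameUsageNode(
    id=minter.mint("usage/"),
    parse=parse_taxonomic_name_usage("Heser stoevi Deltschev 2016, sp. n."),
    mentioned_name_id=minter.mint("name/"),
    container_id=nomenclature.id,
)
add_name_usage(graph, usage)

closure = contains_closure(graph)
print(f"graph: {len(graph)} triples")
print(f"asserted contains edges: 3, closure size: {len(closure)}")
print("article contains the usage transitively:",
      (root.id, usage.id) in closure)

# The closure adds the inferred ancestor pairs (article→nomenclature,
# article→usage, treatment→usage) without materializing them in the graph.
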