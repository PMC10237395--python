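"""Find a term by a colloquial synonym and show its context.

Labels and all synonyms are indexed, so the query 'dog' returns the term
labeled 'Canis lupus familiaris' along with its parent, children and
OntoBee / OLS lookup links.
"""

from ontoscape import build_graph, search_terms, term_context
from ontoscape.ingest import RawTerm, RawTermSet

obo = "http://purl.obolibrary.org/obo/"
terms = [
    RawTerm(iri=obo + "TAX_0000001", label="organism"),
    RawTerm(iri=obo + "TAX_0000002", label="Canis lupus familiaris",
            synonyms=["dog"], definition="The domestic dog.",
            superclass_iris=[obo + "TAX_0000001"]),
    RawTerm(iri=obo + "TAX_0000003", label="Felis catus", synonyms=["cat"],
            superclass_iris=[obo + "TAX_0000001"]),
]
graph = build_graph(RawTermSet(terms={t.iri: t for t in terms},
                               source_identifier="inline", format="rdfxml"))

hits = search_terms("dog", graph)
print(f"query 'dog' -> {[h.label for h in hits]}")
ctx = term_context(hits[0].iri, graph)
print(f"definition: {ctx.definition}")
print(f"parent: {ctx.parent.label}")
print(f"OntoBee: {ctx.ontobee_url}")
print(f"OLS:     {ctx.ols_url}")
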