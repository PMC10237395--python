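"""Label and synonym search, plus per-term context with lookup-service links.

Search is case-insensitive substring matching over labels and all synonym
scopes, so a colloquial query like "dog" finds a term labeled
"Canis lupus familiaris" through its synonym.  Ranking: label-prefix
matches first, then label substrings, then synonym matches; ties break
alphabetically by label.  An empty query lists every term (the pull-down
behaviour).
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from typing import Optional

from .hierarchy import OntologyGraph, TermNode

__all__ = ["TermContext", "search_terms", "term_context", "ontobee_url", "ols_url"]


def _sort_key(node: TermNode) -> tuple[str, str]:
    return ((node.label or "").lower(), node.iri)


def search_terms(query: str, graph: OntologyGraph) -> list[TermNode]:
    """Ranked substring search over labels and synonyms.

    Empty query returns all terms in label order.
    """
    q = query.strip().lower()
    nodes = sorted(graph.nodes.values(), key=_sort_key)
    if not q:
        return nodes
    label_prefix: list[TermNode] = []
    label_sub: list[TermNode] = []
    synonym_hits: list[TermNode] = []
    for node in nodes:
        label = (node.label or "").lower()
        if label.startswith(q):
            label_prefix.append(node)
        elif q in label:
            label_sub.append(node)
        elif any(q in s.lower() for s in node.synonyms):
            synonym_hits.append(node)
    return label_prefix + label_sub + synonym_hits


def ontobee_url(iri: str, prefix: str) -> str:
    """OntoBee term page; carries the unmodified IRI as a query parameter."""
    return f"https://ontobee.org/ontology/{prefix}?iri={iri}"


def ols_url(iri: str, prefix: str) -> str:
    """EMBL-EBI Ontology Lookup Service term page.

    OLS addresses terms by lowercased ontology id and a *double*
    percent-encoded IRI path segment.
    """
    once = urllib.parse.quote(iri, safe="")
    twice = urllib.parse.quote(once, safe="")
    return f"https://www.ebi.ac.uk/ols4/ontologies/{prefix.lower()}/classes/{twice}"


@dataclass
class TermContext:
    term: TermNode
    parent: Optional[TermNode]
    children: list[TermNode]
    definition: Optional[str]
    ontobee_url: str
    ols_url: str
    #: superclasses suppressed by the first-parent rule, if any
    suppressed_parents: list[str] = field(default_factory=list)


def term_context(iri: str, graph: OntologyGraph) -> TermContext:
    """Parent, children, definition, and lookup-service links for one term."""
    if iri not in graph.nodes:
        raise KeyError(f"term not found in graph: {iri}")
    node = graph.nodes[iri]
    parent = graph.nodes.get(node.parent) if node.parent else None
    children = sorted(
        (graph.nodes[c] for c, p in graph.edges if p == iri), key=_sort_key
    )
    suppressed = [p for c, p in graph.dropped_edges if c == iri]
    return TermContext(
        term=node,
        parent=parent,
        children=children,
        definition=node.definition,
        ontobee_url=ontobee_url(iri, node.prefix),
        ols_url=ols_url(iri, node.prefix),
        suppressed_parents=suppressed,
    )
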