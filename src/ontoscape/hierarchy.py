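"""Turn raw class records into a rooted forest.

OWL allows multiple superclasses per class; the rendered hierarchy keeps only
the first superclass listed in the source document, so every node has at most
one parent and the class graph becomes a forest.  Classes with no (surviving)
superclass become roots; roots other than ``owl:Thing`` are "standalone"
roots, drawn disconnected.  Deprecated terms may be filtered out, with their
non-deprecated descendants re-parented to the nearest retained ancestor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .ingest import OWL_THING, RawTermSet, extract_prefix

__all__ = ["TermNode", "OntologyGraph", "build_graph", "compute_depths", "prune_depth"]

logger = logging.getLogger(__name__)


@dataclass
class TermNode:
    iri: str
    prefix: str
    label: Optional[str] = None
    synonyms: list[str] = field(default_factory=list)
    definition: Optional[str] = None
    deprecated: bool = False
    parent: Optional[str] = None
    depth: int = 0
    pinned: bool = False


@dataclass
class OntologyGraph:
    """Forest of TermNodes with single chosen-parent edges."""

    nodes: dict[str, TermNode]
    #: (child IRI, parent IRI) pairs; exactly one per non-root node
    edges: list[tuple[str, str]]
    roots: list[str]
    #: roots that are neither owl:Thing nor connected beneath it
    standalone_roots: list[str]
    #: multi-inheritance edges suppressed by the first-parent rule,
    #: as (child, dropped_parent) — reportable, never rendered
    dropped_edges: list[tuple[str, str]] = field(default_factory=list)

    def children_of(self, iri: str) -> list[str]:
        return [c for c, p in self.edges if p == iri]

    def max_depth(self) -> int:
        return max((n.depth for n in self.nodes.values()), default=0)


def _would_cycle(child: str, candidate_parent: str, parent_of: dict[str, str]) -> bool:
    """True if making candidate_parent the parent of child closes a cycle."""
    cur: Optional[str] = candidate_parent
    while cur is not None:
        if cur == child:
            return True
        cur = parent_of.get(cur)
    return False


def build_graph(raw: RawTermSet, hide_deprecated: bool = True) -> OntologyGraph:
    """Build the single-parent forest from a parsed term set.

    The parent of each term is the first superclass listed in the document
    that (a) survives filtering and (b) does not close a cycle.  A term whose
    listed superclasses all fail becomes a standalone root — unless
    ``hide_deprecated`` removed its only listed parents, in which case it
    re-parents to the nearest retained ancestor along the first-listed chain.
    ``owl:Thing`` is materialized as a node whenever it is declared or named
    as a superclass.
    """
    retained = {
        iri: t for iri, t in raw.terms.items() if not (hide_deprecated and t.deprecated)
    }

    # Materialize owl:Thing if anything references or declares it.
    references_thing = any(
        OWL_THING in t.superclass_iris for t in retained.values()
    ) or OWL_THING in raw.terms
    nodes: dict[str, TermNode] = {}
    if references_thing and OWL_THING not in retained:
        nodes[OWL_THING] = TermNode(iri=OWL_THING, prefix="owl", label="Thing")

    for iri, t in retained.items():
        nodes[iri] = TermNode(
            iri=iri,
            prefix=extract_prefix(iri),
            label=t.label,
            synonyms=list(t.synonyms),
            definition=t.definition,
            deprecated=t.deprecated,
        )

    # Nearest retained ancestor along a (possibly deprecated) term's own
    # first-listed chain; used only when a child lost all listed parents.
    def climb_to_retained(start_iri: str, avoid: str) -> Optional[str]:
        seen = {avoid}
        cur = start_iri
        while cur is not None and cur not in seen:
            seen.add(cur)
            if cur in nodes:
                return cur
            t = raw.terms.get(cur)
            cur = t.superclass_iris[0] if t and t.superclass_iris else None
        return None

    parent_of: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    dropped: list[tuple[str, str]] = []

    for iri, t in raw.terms.items():  # source order => deterministic cycle breaking
        if iri not in nodes:
            continue
        chosen: Optional[str] = None
        for sup in t.superclass_iris:
            if sup not in nodes:
                continue  # deprecated-filtered or ghost reference
            if _would_cycle(iri, sup, parent_of):
                logger.warning("superclass %s of %s would close a cycle; skipped", sup, iri)
                continue
            if chosen is None:
                chosen = sup
            else:
                dropped.append((iri, sup))
        if chosen is None and hide_deprecated and t.superclass_iris:
            first = t.superclass_iris[0]
            anc = climb_to_retained(first, avoid=iri)
            if anc is not None and not _would_cycle(iri, anc, parent_of):
                chosen = anc
        if chosen is not None:
            parent_of[iri] = chosen
            nodes[iri].parent = chosen
            edges.append((iri, chosen))

    roots = [iri for iri, n in nodes.items() if n.parent is None]
    standalone = [r for r in roots if r != OWL_THING]
    graph = OntologyGraph(
        nodes=nodes,
        edges=edges,
        roots=roots,
        standalone_roots=standalone,
        dropped_edges=dropped,
    )
    compute_depths(graph)
    return graph


def compute_depths(graph: OntologyGraph) -> OntologyGraph:
    """Assign depth = edge count to root (roots at 0), breadth-first."""
    children: dict[str, list[str]] = {}
    for child, parent in graph.edges:
        children.setdefault(parent, []).append(child)
    frontier = list(graph.roots)
    for r in frontier:
        graph.nodes[r].depth = 0
    while frontier:
        nxt: list[str] = []
        for iri in frontier:
            d = graph.nodes[iri].depth
            for c in children.get(iri, []):
                graph.nodes[c].depth = d + 1
                nxt.append(c)
        frontier = nxt
    return graph


def prune_depth(graph: OntologyGraph, max_depth: int) -> OntologyGraph:
    """Keep only nodes with depth <= max_depth (depths must be computed)."""
    if max_depth < 0:
        raise ValueError(f"max_depth must be non-negative, got {max_depth}")
    keep = {iri for iri, n in graph.nodes.items() if n.depth <= max_depth}
    nodes = {iri: graph.nodes[iri] for iri in graph.nodes if iri in keep}
    edges = [(c, p) for c, p in graph.edges if c in keep and p in keep]
    roots = [r for r in graph.roots if r in keep]
    standalone = [r for r in graph.standalone_roots if r in keep]
    dropped = [(c, p) for c, p in graph.dropped_edges if c in keep]
    return OntologyGraph(
        nodes=nodes, edges=edges, roots=roots,
        standalone_roots=standalone, dropped_edges=dropped,
    )
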