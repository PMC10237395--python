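"""Shared fixtures: tiny hand-built ontologies and generated ones."""

from __future__ import annotations

import pytest

from ontoscape.hierarchy import build_graph
from ontoscape.ingest import RawTerm, RawTermSet

OBO = "http://purl.obolibrary.org/obo/"


def make_term_set(terms: list[RawTerm]) -> RawTermSet:
    return RawTermSet(
        terms={t.iri: t for t in terms}, source_identifier="inline", format="rdfxml"
    )


def iri(local: str) -> str:
    return OBO + local


@pytest.fixture
def chain_raw() -> RawTermSet:
    """Root -> a -> b -> c chain (depths 0..3)."""
    return make_term_set([
        RawTerm(iri=iri("TST_0000001"), label="root"),
        RawTerm(iri=iri("TST_0000002"), label="a", superclass_iris=[iri("TST_0000001")]),
        RawTerm(iri=iri("TST_0000003"), label="b", superclass_iris=[iri("TST_0000002")]),
        RawTerm(iri=iri("TST_0000004"), label="c", superclass_iris=[iri("TST_0000003")]),
    ])


@pytest.fixture
def chain_graph(chain_raw):
    return build_graph(chain_raw)


@pytest.fixture
def binary_tree_raw() -> RawTermSet:
    """Full binary tree of depth 3: 15 nodes, IRIs in level/DFS-compatible order."""
    terms = [RawTerm(iri=iri("BIN_0000001"), label="n1")]
    for i in range(2, 16):
        terms.append(
            RawTerm(
                iri=iri(f"BIN_{i:07d}"),
                label=f"n{i}",
                superclass_iris=[iri(f"BIN_{i // 2:07d}")],
            )
        )
    return make_term_set(terms)


@pytest.fixture
def dog_raw() -> RawTermSet:
    """The colloquial-synonym search fixture."""
    return make_term_set([
        RawTerm(iri=iri("TAX_0000001"), label="organism"),
        RawTerm(
            iri=iri("TAX_0000002"),
            label="Canis lupus familiaris",
            synonyms=["dog"],
            definition="The domestic dog.",
            superclass_iris=[iri("TAX_0000001")],
        ),
        RawTerm(iri=iri("TAX_0000003"), label="Felis catus",
                synonyms=["cat"], superclass_iris=[iri("TAX_0000001")]),
    ])
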