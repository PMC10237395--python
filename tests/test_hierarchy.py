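"""Forest construction: first-parent rule, roots, deprecation, depths, pruning."""

import pytest

from ontoscape.fixtures import FixtureSpec, generate_ontology
from ontoscape.hierarchy import build_graph, prune_depth
from ontoscape.ingest import OWL_THING, RawTerm

from conftest import iri, make_term_set


def test_first_listed_superclass_wins():
    raw = make_term_set([
        RawTerm(iri=iri("EX_0000001"), label="A"),
        RawTerm(iri=iri("EX_0000002"), label="B"),
        RawTerm(iri=iri("EX_0000003"), label="C",
                superclass_iris=[iri("EX_0000001"), iri("EX_0000002")]),
    ])
    g = build_graph(raw)
    assert g.nodes[iri("EX_0000003")].parent == iri("EX_0000001")
    assert g.dropped_edges == [(iri("EX_0000003"), iri("EX_0000002"))]


def test_term_without_superclass_is_standalone_root():
    raw = make_term_set([
        RawTerm(iri=iri("EX_0000001"), label="lonely"),
        RawTerm(iri=iri("EX_0000002"), label="child",
                superclass_iris=[iri("EX_0000001")]),
    ])
    g = build_graph(raw)
    assert g.roots == [iri("EX_0000001")]
    assert g.standalone_roots == [iri("EX_0000001")]


def test_owl_thing_materialized_when_referenced():
    raw = make_term_set([
        RawTerm(iri=iri("EX_0000001"), superclass_iris=[OWL_THING]),
    ])
    g = build_graph(raw)
    assert OWL_THING in g.nodes
    assert g.nodes[iri("EX_0000001")].parent == OWL_THING
    # owl:Thing is a root but not a standalone root
    assert OWL_THING in g.roots and OWL_THING not in g.standalone_roots


def test_owl_thing_omitted_when_unreferenced():
    raw = make_term_set([RawTerm(iri=iri("EX_0000001"))])
    g = build_graph(raw)
    assert OWL_THING not in g.nodes


def test_ghost_superclasses_dropped():
    raw = make_term_set([
        RawTerm(iri=iri("EX_0000001"),
                superclass_iris=["http://example.org/ghost", iri("EX_0000002")]),
        RawTerm(iri=iri("EX_0000002")),
    ])
    g = build_graph(raw)
    assert g.nodes[iri("EX_0000001")].parent == iri("EX_0000002")


def test_hide_deprecated_removes_deprecated_leaves():
    terms = [RawTerm(iri=iri("DEP_0000001"), label="root")]
    for k in range(2, 11):
        terms.append(RawTerm(
            iri=iri(f"DEP_{k:07d}"),
            superclass_iris=[iri("DEP_0000001")],
            deprecated=k in (9, 10),
        ))
    g = build_graph(make_term_set(terms), hide_deprecated=True)
    assert len(g.nodes) == 8


def test_show_deprecated_is_identity():
    terms = [
        RawTerm(iri=iri("DEP_0000001")),
        RawTerm(iri=iri("DEP_0000002"), deprecated=True,
                superclass_iris=[iri("DEP_0000001")]),
    ]
    g = build_graph(make_term_set(terms), hide_deprecated=False)
    assert iri("DEP_0000002") in g.nodes
    assert g.nodes[iri("DEP_0000002")].deprecated


def test_descendants_of_deprecated_internal_node_reparent():
    raw = make_term_set([
        RawTerm(iri=iri("EX_0000001"), label="keep-root"),
        RawTerm(iri=iri("EX_0000002"), label="dead", deprecated=True,
                superclass_iris=[iri("EX_0000001")]),
        RawTerm(iri=iri("EX_0000003"), label="orphan",
                superclass_iris=[iri("EX_0000002")]),
    ])
    g = build_graph(raw, hide_deprecated=True)
    assert iri("EX_0000002") not in g.nodes
    # re-parented to the nearest retained ancestor, not left standalone
    assert g.nodes[iri("EX_0000003")].parent == iri("EX_0000001")


def test_second_listed_superclass_preferred_over_climbing():
    # first-listed parent is deprecated, second survives: the second wins
    raw = make_term_set([
        RawTerm(iri=iri("EX_0000001")),
        RawTerm(iri=iri("EX_0000002"), deprecated=True,
                superclass_iris=[iri("EX_0000001")]),
        RawTerm(iri=iri("EX_0000004")),
        RawTerm(iri=iri("EX_0000003"),
                superclass_iris=[iri("EX_0000002"), iri("EX_0000004")]),
    ])
    g = build_graph(raw, hide_deprecated=True)
    assert g.nodes[iri("EX_0000003")].parent == iri("EX_0000004")


def test_cycle_breaking_falls_back_to_next_superclass():
    raw = make_term_set([
        RawTerm(iri=iri("CYC_0000001"), superclass_iris=[iri("CYC_0000002")]),
        RawTerm(iri=iri("CYC_0000002"),
                superclass_iris=[iri("CYC_0000001"), iri("CYC_0000003")]),
        RawTerm(iri=iri("CYC_0000003")),
    ])
    g = build_graph(raw)  # must not crash
    assert g.nodes[iri("CYC_0000001")].parent == iri("CYC_0000002")
    assert g.nodes[iri("CYC_0000002")].parent == iri("CYC_0000003")


def test_full_cycle_becomes_standalone_root():
    raw = make_term_set([
        RawTerm(iri=iri("CYC_0000001"), superclass_iris=[iri("CYC_0000002")]),
        RawTerm(iri=iri("CYC_0000002"), superclass_iris=[iri("CYC_0000001")]),
    ])
    g = build_graph(raw)
    roots = set(g.roots)
    assert len(roots) == 1 and roots <= {iri("CYC_0000001"), iri("CYC_0000002")}


def test_depths_on_chain(chain_graph):
    depths = sorted(n.depth for n in chain_graph.nodes.values())
    assert depths == [0, 1, 2, 3]


def test_two_root_forest_both_depth_zero():
    raw = make_term_set([
        RawTerm(iri=iri("EX_0000001")),
        RawTerm(iri=iri("EX_0000002")),
        RawTerm(iri=iri("EX_0000003"), superclass_iris=[iri("EX_0000001")]),
    ])
    g = build_graph(raw)
    assert g.nodes[iri("EX_0000001")].depth == 0
    assert g.nodes[iri("EX_0000002")].depth == 0
    assert g.nodes[iri("EX_0000003")].depth == 1


@pytest.mark.parametrize("max_depth,expected", [(1, 2), (3, 4), (10, 4)])
def test_prune_depth_on_chain(chain_graph, max_depth, expected):
    assert len(prune_depth(chain_graph, max_depth).nodes) == expected


def test_prune_depth_binary_tree(binary_tree_raw):
    g = build_graph(binary_tree_raw)
    assert len(prune_depth(g, 2).nodes) == 7


def test_prune_depth_negative_rejected(chain_graph):
    with pytest.raises(ValueError):
        prune_depth(chain_graph, -1)


def brute_force_first_parent(raw, hide_deprecated=True):
    """Independent oracle: first listed superclass that survives filtering.

    Ignores cycles (the generator never produces any among first parents).
    """
    retained = {
        i for i, t in raw.terms.items() if not (hide_deprecated and t.deprecated)
    }
    expected = {}
    for i, t in raw.terms.items():
        if i not in retained:
            continue
        expected[i] = next((s for s in t.superclass_iris if s in retained), None)
    return expected


@pytest.mark.parametrize("seed", range(8))
def test_parent_choice_matches_brute_force_oracle(seed):
    raw, _ = generate_ontology(
        FixtureSpec(n_terms=60, n_prefixes=4, multi_parent_fraction=0.3,
                    deprecated_fraction=0.05, seed=seed)
    )
    g = build_graph(raw, hide_deprecated=True)
    expected = brute_force_first_parent(raw)
    for iri_, parent in expected.items():
        assert g.nodes[iri_].parent == parent, iri_


@pytest.mark.parametrize("seed", range(5))
def test_forest_invariant(seed):
    raw, _ = generate_ontology(
        FixtureSpec(n_terms=120, n_prefixes=3, multi_parent_fraction=0.25, seed=seed)
    )
    g = build_graph(raw)
    assert len(g.edges) == len(g.nodes) - len(g.roots)
    # acyclic: walking up from any node terminates at a root
    for iri_ in g.nodes:
        seen = set()
        cur = iri_
        while cur is not None:
            assert cur not in seen
            seen.add(cur)
            cur = g.nodes[cur].parent
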