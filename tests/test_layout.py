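"""Layout: seeds, spawning, stratification, pins, slices, tidy trees."""

import math

import numpy as np
import pytest

from ontoscape.fixtures import FixtureSpec, generate_ontology, scaffold_fixture, to_owl_xml
from ontoscape.hierarchy import OntologyGraph, build_graph
from ontoscape.ingest import RawTerm
from ontoscape.layout import (
    LayoutParams,
    LayoutStats,
    PinConfig,
    derive_seed,
    layout,
    layout_all_at_once,
    median_parent_distance,
    slice_layout,
    spawn_position,
    tidy_tree_2d,
)

from conftest import iri, make_term_set

FAST = LayoutParams(max_iter_per_generation=120)


def fixture_iris(n=200, seed=0):
    raw, _ = generate_ontology(FixtureSpec(n_terms=n, seed=seed))
    return list(raw.terms)


class TestDeriveSeed:
    def test_pure(self):
        assert derive_seed(42, "http://x/A") == derive_seed(42, "http://x/A")

    def test_distinct_iris_distinct_seeds(self):
        iris = fixture_iris()
        seeds = {derive_seed(7, i) for i in iris}
        assert len(seeds) == len(iris)

    def test_master_seed_changes_every_seed(self):
        iris = fixture_iris()
        for i in iris:
            assert derive_seed(1, i) != derive_seed(2, i)


class TestSpawnPosition:
    def test_offset_bounded_by_jitter_radius(self):
        for s in range(100):
            x, z = spawn_position((0.0, 0.0), derive_seed(s, "x"), 30.0)
            assert 0 < math.hypot(x, z) <= 30.0

    def test_deterministic(self):
        a = spawn_position((5.0, -3.0), 123456789, 30.0)
        assert a == spawn_position((5.0, -3.0), 123456789, 30.0)

    def test_no_sibling_coincidence_over_1000_seeds(self):
        pts = {
            spawn_position((0.0, 0.0), derive_seed(9, f"http://x/{k}"), 30.0)
            for k in range(1000)
        }
        assert len(pts) == 1000


def test_single_pinned_root_stays_exactly_at_pin():
    raw = make_term_set([RawTerm(iri=iri("PIN_0000001"), label="solo")])
    g = build_graph(raw)
    pins = PinConfig(entries={iri("PIN_0000001"): (12.5, 0.0, -7.25)})
    coords = layout(g, pins=pins, params=FAST)
    assert coords[iri("PIN_0000001")] == (12.5, 0.0, -7.25)


def test_chain_y_coordinates_stratified(chain_graph):
    coords = layout(chain_graph, params=FAST)
    ys = sorted(y for _, y, _ in coords.values())
    assert ys == [-300.0, -200.0, -100.0, 0.0]


def test_two_runs_bitwise_identical():
    raw, _ = generate_ontology(FixtureSpec(n_terms=150, n_prefixes=4, seed=2))
    g = build_graph(raw)
    assert layout(g, params=FAST) == layout(g, params=FAST)


def test_stratification_exact_integer_multiples():
    raw, _ = generate_ontology(FixtureSpec(n_terms=180, seed=4))
    g = build_graph(raw)
    coords = layout(g, params=FAST)
    for iri_, (_, y, _) in coords.items():
        assert y == -g.nodes[iri_].depth * FAST.tier_spacing


def test_pin_fidelity_exact():
    pins, raw = scaffold_fixture()
    g = build_graph(raw)
    coords = layout(g, pins=pins)
    for iri_, xyz in pins.resolve(g).items():
        assert coords[iri_] == xyz


def test_unresolved_pin_entries_ignored_with_warning(caplog):
    raw = make_term_set([RawTerm(iri=iri("PIN_0000001"))])
    g = build_graph(raw)
    pins = PinConfig(entries={"NOPE:0000099": (0.0, 0.0, 0.0)})
    with caplog.at_level("WARNING"):
        layout(g, pins=pins, params=FAST)
    assert any("NOPE:0000099" in r.message for r in caplog.records)


def test_pin_config_json_roundtrip(tmp_path):
    pins, _ = scaffold_fixture()
    pins.to_json(tmp_path / "pins.json")
    again = PinConfig.from_json(tmp_path / "pins.json")
    assert again.entries == pins.entries


def test_adding_deep_leaf_barely_moves_upper_strata():
    """Generational cooling keeps settled upper tiers near their positions."""
    raw, _ = generate_ontology(FixtureSpec(n_terms=60, branching_mean=2.5, seed=6))
    g1 = build_graph(raw)
    coords1 = layout(g1)
    deepest = max(g1.nodes.values(), key=lambda n: (n.depth, n.iri))
    extra = RawTerm(iri=iri("ZZZ_9999999"), label="extra leaf",
                    superclass_iris=[deepest.iri])
    raw2 = make_term_set(list(raw.terms.values()) + [extra])
    g2 = build_graph(raw2)
    coords2 = layout(g2)
    params = LayoutParams()
    for iri_, n in g1.nodes.items():
        if n.depth == 1:
            a, b = np.array(coords1[iri_]), np.array(coords2[iri_])
            assert np.linalg.norm(a - b) < params.jitter_radius


def test_empty_graph_rejected():
    g = OntologyGraph(nodes={}, edges=[], roots=[], standalone_roots=[])
    with pytest.raises(ValueError):
        layout(g)


class TestTidyTree:
    def test_single_node_at_origin(self):
        raw = make_term_set([RawTerm(iri=iri("T_0000001"))])
        g = build_graph(raw)
        assert tidy_tree_2d(g) == {iri("T_0000001"): (0.0, 0.0)}

    def test_parent_centered_over_two_leaves(self):
        raw = make_term_set([
            RawTerm(iri=iri("T_0000001")),
            RawTerm(iri=iri("T_0000002"), superclass_iris=[iri("T_0000001")]),
            RawTerm(iri=iri("T_0000003"), superclass_iris=[iri("T_0000001")]),
        ])
        uv = tidy_tree_2d(build_graph(raw))
        u1 = uv[iri("T_0000002")][0]
        u2 = uv[iri("T_0000003")][0]
        assert uv[iri("T_0000001")] == ((u1 + u2) / 2.0, 0.0)
        assert u1 != u2

    def test_binary_tree_leaves_increase_in_iri_order(self):
        terms = [RawTerm(iri=iri("B_1"))]
        for label in ("10", "11"):
            terms.append(RawTerm(iri=iri(f"B_{label}"), superclass_iris=[iri("B_1")]))
        for label in ("100", "101", "110", "111"):
            terms.append(RawTerm(iri=iri(f"B_{label}"),
                                 superclass_iris=[iri(f"B_{label[:2]}")]))
        uv = tidy_tree_2d(build_graph(make_term_set(terms)))
        leaf_us = [uv[iri(f"B_{l}")][0] for l in ("100", "101", "110", "111")]
        assert leaf_us == sorted(leaf_us)
        assert len(set(leaf_us)) == 4

    def test_depth_strata_in_plane(self):
        raw = make_term_set([
            RawTerm(iri=iri("T_0000001")),
            RawTerm(iri=iri("T_0000002"), superclass_iris=[iri("T_0000001")]),
        ])
        uv = tidy_tree_2d(build_graph(raw))
        assert uv[iri("T_0000002")][1] == -100.0


class TestSliceLayout:
    def test_shallow_graph_identical_to_layout(self, chain_graph):
        full = layout(chain_graph, params=FAST)
        sliced = slice_layout(chain_graph, params=FAST, scaffold_depth=5)
        assert full == sliced

    def test_slice_nodes_coplanar_with_anchor(self):
        # root -> anchor -> chain of 3 below scaffold_depth=1
        terms = [RawTerm(iri=iri("S_0000001"))]
        terms.append(RawTerm(iri=iri("S_0000002"), superclass_iris=[iri("S_0000001")]))
        prev = "S_0000002"
        for k in (3, 4, 5):
            terms.append(RawTerm(iri=iri(f"S_{k:07d}"), superclass_iris=[iri(prev)]))
            prev = f"S_{k:07d}"
        g = build_graph(make_term_set(terms))
        coords = slice_layout(g, params=FAST, scaffold_depth=1)
        ax, _, az = coords[iri("S_0000002")]
        # plane normal is perpendicular to both vertical and the radial dir
        norm = math.hypot(ax, az)
        nx, nz = -az / norm, ax / norm
        for k in (3, 4, 5):
            x, _, z = coords[iri(f"S_{k:07d}")]
            assert abs((x - ax) * nx + (z - az) * nz) < 1e-9

    def test_distinct_anchors_distinct_planes(self):
        terms = [RawTerm(iri=iri("S_0000001"))]
        for a in (2, 3):
            terms.append(RawTerm(iri=iri(f"S_{a:07d}"),
                                 superclass_iris=[iri("S_0000001")]))
            terms.append(RawTerm(iri=iri(f"S_{a + 10:07d}"),
                                 superclass_iris=[iri(f"S_{a:07d}")]))
        g = build_graph(make_term_set(terms))
        coords = slice_layout(g, params=FAST, scaffold_depth=1)
        az1 = math.atan2(coords[iri("S_0000002")][2], coords[iri("S_0000002")][0])
        az2 = math.atan2(coords[iri("S_0000003")][2], coords[iri("S_0000003")][0])
        assert abs(az1 - az2) > 1e-6

    def test_slice_preserves_stratification(self):
        raw, _ = generate_ontology(FixtureSpec(n_terms=120, seed=8))
        g = build_graph(raw)
        coords = slice_layout(g, params=FAST, scaffold_depth=2)
        for iri_, (_, y, _) in coords.items():
            assert y == -g.nodes[iri_].depth * FAST.tier_spacing


def test_generational_beats_random_initialization_on_parent_distance():
    raw, _ = generate_ontology(FixtureSpec(n_terms=300, seed=42))
    g = build_graph(raw)
    stats = LayoutStats()
    cg = layout(g, stats=stats)
    ca = layout_all_at_once(g, iteration_budget=stats.total_iterations)
    assert median_parent_distance(g, cg) <= median_parent_distance(g, ca)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        LayoutParams(damping=1.0)
    with pytest.raises(ValueError):
        LayoutParams(jitter_radius=0.0)
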