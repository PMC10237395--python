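"""Generate a synthetic multi-prefix ontology, lay it out, export a scene.

Prints the node/edge/legend counts and the per-prefix legend.  The layout is
deterministic: rerunning this script reproduces the same coordinates.
"""

from pathlib import Path

from ontoscape import (
    FixtureSpec,
    LayoutParams,
    build_graph,
    build_scene,
    generate_ontology,
    layout,
    parse_ontology,
    render_html,
    write_scene,
)

out = Path("scratch")
out.mkdir(exist_ok=True)

spec = FixtureSpec(n_terms=400, n_prefixes=6, multi_parent_fraction=0.15,
                   deprecated_fraction=0.05, synonym_fraction=0.3, seed=42)
generate_ontology(spec, out / "demo.owl")

raw = parse_ontology(out / "demo.owl")
graph = build_graph(raw, hide_deprecated=True)  # deprecated leaves vanish
coords = layout(graph, params=LayoutParams(master_seed=1))
scene = build_scene(graph, coords, source_identifier=str(out / "demo.owl"))

write_scene(scene, out / "demo.scene.json")
render_html(scene, path=out / "demo.html")

print(f"{len(scene.nodes)} nodes, {len(scene.edges)} edges "
      f"({len(graph.dropped_edges)} multi-inheritance edges suppressed)")
print("prefix legend (count = terms drawn in that ontology's color):")
for entry in scene.legend:
    print(f"  {entry.prefix:10s} {entry.term_count:4d}  rgb{entry.color}")
print(f"scene -> {out / 'demo.scene.json'}, interactive view -> {out / 'demo.html'}")
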