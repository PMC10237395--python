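"""Hybrid view: 3D upper levels, deeper branches as flat vertical slices.

Everything at depth <= 2 keeps the 3D force layout; each deeper subtree is
drawn as a 2D tidy tree in the vertical half-plane through its depth-2
anchor, which separates labels for medium-sized ontologies.
"""

import math

from ontoscape import FixtureSpec, build_graph, generate_ontology, slice_layout

raw, _ = generate_ontology(FixtureSpec(n_terms=300, n_prefixes=4, seed=11))
graph = build_graph(raw)
coords = slice_layout(graph, scaffold_depth=2)

anchors = [iri for iri, n in graph.nodes.items() if n.depth == 2]
deep = [iri for iri, n in graph.nodes.items() if n.depth > 2]
azimuths = {round(math.atan2(z, x), 3) for iri in anchors for x, _, z in [coords[iri]]}
print(f"{len(graph.nodes)} nodes: {len(graph.nodes) - len(deep)} in the 3D "
      f"upper layout, {len(deep)} in {len(anchors)} vertical slices")
print(f"distinct slice azimuths: {len(azimuths)} "
      "(each anchor's subtree hangs in its own half-plane)")
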