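# ontoscape

Deterministic 3D layout of OWL ontology class hierarchies.

Biomedical reference ontologies (the OBO Foundry families: GO, CHEBI, UBERON,
OBI, …) are large `rdfs:subClassOf` graphs. Flat indented trees hide their
shape: how deep each branch runs, where ontologies import one another, and
whether the upper levels conform to a shared upper-level model. `ontoscape`
turns an OWL file into a navigable 3D *term landscape*:

- **Depth stratification.** Every class sits on a horizontal tier at
  `y = −depth × tier_spacing`, so vertical position *is* hierarchy depth.
- **Single-parent forest.** Multiple inheritance is reduced to a tree by
  keeping each class's *first listed* superclass (the order the axioms appear
  in the document); suppressed parents remain inspectable per term.
- **Deterministic force layout.** Within each tier, nodes spread out in the
  x–z plane under parent springs and pairwise repulsion. All randomness is
  derived from `sha256(master_seed, IRI)`, so the same file, seed and
  parameters reproduce byte-identical coordinates on any machine.
- **Generational insertion.** Depth levels are added one at a time, each
  child spawning beside its parent, which keeps subtrees together instead of
  scattering late-inserted nodes to the periphery.
- **Pinned upper-level scaffold.** A pin file fixes chosen terms (e.g. a
  BFO-like upper ontology) at exact coordinates; pinned terms never move, so
  every ontology hung beneath the scaffold presents the same summit.
- **Styling, search, export.** Per-ontology-prefix colors with a legend,
  depth-scaled edge thickness, label/synonym search with OntoBee and OLS
  links, JSON scene + GraphML export, a self-contained interactive HTML
  viewer, and a coordinate cache keyed on structure + parameters.

## Quick start (CLI)

```bash
# make a synthetic 200-term, 3-prefix ontology to play with
ontoscape generate --n-terms 200 --n-prefixes 3 --seed 5 --out demo.owl

# lay it out, write a scene and an interactive viewer
ontoscape layout demo.owl --scene-out demo.scene.json --html-out demo.html --summary
```

prints

```
{"nodes": 200, "edges": 199, "legend_entries": 3, "dropped_multiparent_edges": 0,
 "structure_hash": "34bd3ff1d33b...", "cache_hit": false, "scene_out": "demo.scene.json"}
```

Other subcommands: `ontoscape search FILE QUERY`, `ontoscape context FILE IRI
[--json]`, `ontoscape legend FILE`. `layout` also accepts `--pins FILE.json`,
`--max-depth N`, `--show-deprecated`, `--slice --scaffold-depth N` (hybrid
3D/2D view), `--seed N` and `--cache-dir DIR`. Real ontologies work the same
way: point `layout` at any local `.owl`/`.ttl` file or an OBO PURL.

## Worked example (library)

`examples/render_synthetic.py` generates a 400-term, 6-prefix ontology with
multiple inheritance, deprecated leaves and synonyms, then parses, filters,
lays out and exports it:

```
380 nodes, 379 edges (58 multi-inheritance edges suppressed)
prefix legend (count = terms drawn in that ontology's color):
  CHEBI        73  rgb(170, 110, 40)
  GO           68  rgb(255, 140, 0)
  OBI          68  rgb(255, 255, 255)
  PATO         63  rgb(64, 192, 64)
  CL           60  rgb(60, 120, 255)
  UBERON       48  rgb(240, 100, 200)
scene -> scratch/demo.scene.json, interactive view -> scratch/demo.html
```

400 generated terms minus 20 hidden deprecated leaves leaves 380 drawn nodes;
a tree on 380 nodes has 379 edges, and the 58 extra superclass axioms are
recorded as suppressed parents rather than drawn.

The other examples each print a one-screen, interpreted result:

- `examples/pinned_scaffold.py` — hangs 500 terms beneath the pinned 34-term
  two-pole upper scaffold and verifies no pinned coordinate moved.
- `examples/search_synonyms.py` — finds *Canis lupus familiaris* from the
  query `dog` via its synonym, with OntoBee/OLS links.
- `examples/slice_view.py` — hybrid view: 3D upper levels, deeper subtrees
  drawn as 2D tidy trees in per-anchor vertical half-planes.

## Layout of the package

| Module | Purpose |
| --- | --- |
| `ontoscape.ingest` | OWL/RDF parsing (rdflib) preserving superclass document order |
| `ontoscape.hierarchy` | single-parent forest, depth assignment, deprecation filtering |
| `ontoscape.layout` | deterministic stratified force layout, pins, slices, tidy trees |
| `ontoscape.styling` | prefix color table, hash fallback, edge/node sizing, legend |
| `ontoscape.scene` | scene JSON schema, structure hash, coordinate cache, GraphML |
| `ontoscape.search` | label/synonym search, term context, OntoBee/OLS URLs |
| `ontoscape.fixtures` | synthetic ontology generator and pinned upper scaffold |
| `ontoscape.viewer` | self-contained interactive HTML viewer |
| `ontoscape.cli` | `ontoscape` command line |

Algorithmic details, parameter defaults and limitations are documented in
[`docs/methods.md`](docs/methods.md).
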