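# Methods

This note documents the model, algorithms, parameter defaults and known
limitations of `ontoscape`. Everything described here is implemented in
`src/ontoscape/` and exercised by the test suite.

## 1. Ingestion

`parse_ontology` loads an RDF/XML or Turtle document with rdflib from a local
path or URL (format inferred from the extension/content type unless
`format_hint` is given). It records, per declared `owl:Class` with a
resolvable IRI:

- `rdfs:label` (an English-tagged literal is preferred when several exist),
- synonyms from the four `oboInOwl` synonym properties, deduplicated with
  exact > narrow > broad > related precedence,
- the textual definition (`IAO_0000115`),
- `owl:deprecated`,
- **superclass IRIs in document order.**

Order matters because the forest rule below keeps the *first listed*
superclass. rdflib's RDF/XML and Turtle parsers invoke `Graph.add` in
document encounter order; we capture that order by parsing into a `Graph`
subclass that logs every added triple, rather than re-reading the file by
byte offset. This property is asserted by tests against documents whose
axiom order differs from lexical order.

Superclasses that are blank-node restrictions are ignored (only named
classes can be tree parents). References to classes never declared in the
document are reported as *ghost references*, not silently dropped.

## 2. Single-parent forest

Ontologies use multiple inheritance; a comprehensible landscape needs a
tree. `build_graph` assigns each class at most one drawn parent:

1. Candidate parents are the class's listed superclasses, in document order.
2. With `hide_deprecated=True` (the default), deprecated classes are removed
   from the graph. A candidate is *retained* if it survives this filter.
3. The drawn parent is the **first retained candidate that does not create a
   cycle**. Cycle checks follow drawn parents only; when every candidate
   would close a cycle the class becomes a standalone root and the skipped
   axioms are recorded in `dropped_edges`.
4. If *no* listed superclass survives filtering, the class is re-parented to
   its nearest retained ancestor along the first-listed chain (climbing
   through deprecated intermediates); if the whole chain is deprecated it
   becomes a standalone root.

All non-drawn superclass axioms are kept in `dropped_edges` and surface in
`term_context` as *suppressed parents*. `owl:Thing` is materialized as a
root only when some class lists it explicitly. Depth is the drawn-tree
distance from a root (BFS), so every child's depth is its parent's plus one.

## 3. Layout

### Stratification

Coordinates are `(x, y, z)` with `y = −depth × tier_spacing` **exactly** —
vertical position is assigned, never simulated. The force simulation acts
only in the x–z plane.

### Determinism

Every stochastic quantity derives from
`seed(iri) = first 8 bytes of sha256(master_seed ‖ 0x00 ‖ iri)`. There is no
global random stream, so coordinates do not depend on dict iteration order,
platform, or how many nodes exist; adding an unrelated subtree does not
change another subtree's spawn positions (its final relaxed positions do
change, since forces are global).

### Generational insertion

Nodes enter the simulation one depth level (*generation*) at a time:

1. Roots are placed on a circle (ordered by IRI for determinism); pinned
   nodes go exactly to their pinned coordinates and are never moved.
2. Each new child spawns at its parent's (x, z) plus a seed-derived jitter
   of magnitude in `[0.2 × jitter_radius, jitter_radius]`.
3. The planar simulation relaxes: spring forces along drawn edges
   (`spring_k × displacement`), inverse-square repulsion
   (`repulsion_k / d²`) between node pairs closer than
   `repulsion_cutoff_factor × current mean pairwise deviation` (pairs found
   with a `scipy.spatial.cKDTree`), velocity damping, a per-node per-step
   displacement clamp (`max_step`), and per-iteration annealing
   (`iteration_cooling`). Iteration stops when the max displacement falls
   below `settle_epsilon` or after `max_iter_per_generation` steps.
4. Earlier generations keep simulating but are cooled by
   `generation_cooling^(elapsed generations)`, so established structure
   drifts less as new levels arrive.

Spawning children beside their parents instead of randomly initializing
everything at once is what prevents *ostracism* — late-inserted nodes being
pushed to the hull far from their subtree. `layout_all_at_once` implements
the random-disc-initialization baseline with an equal iteration budget;
`median_parent_distance` (median planar child–parent distance) is the
comparison statistic. On 500-node fixtures the generational scheme's median
is roughly half the baseline's (≈45 vs ≈83 length units at the defaults;
`scripts/acceptance.py` recomputes this).

### Parameters

`LayoutParams` (frozen dataclass; `.digest()` feeds the cache key):

| Parameter | Default | Units | Rationale |
| --- | --- | --- | --- |
| `tier_spacing` | 100.0 | length | one depth level per 100 units |
| `repulsion_k` | 500.0 | force·length² | spreads siblings without overwhelming springs |
| `spring_k` | 0.1 | force/length | keeps children near parents |
| `damping` | 0.6 | — | velocity retained per step |
| `max_step` | 25.0 | length | per-step displacement clamp; prevents oscillation in large generations |
| `iteration_cooling` | 0.97 | — | per-iteration annealing factor; guarantees settling |
| `generation_cooling` | 0.3 | — | per-elapsed-generation temperature for old nodes |
| `max_iter_per_generation` | 300 | steps | budget per depth level |
| `settle_epsilon` | 0.1 | length | convergence threshold on max displacement |
| `jitter_radius` | 30.0 | length | spawn offset scale; also the tidy-tree leaf width |
| `repulsion_cutoff_factor` | 1.5 | — | KD-tree neighbor cutoff as a multiple of mean pairwise deviation |
| `min_separation` | 2.0 | length | distance floor inside the repulsion law |
| `master_seed` | 1 | — | root of all per-IRI seeds |

The force constants, clamp and annealing schedule are engineering choices
tuned for guaranteed settling within the iteration budget, not fitted to any
external target: without `max_step`/`iteration_cooling`, generations with
several hundred simultaneous insertions oscillate at the iteration cap. The
cutoff factor 1.5 (rather than a larger multiple of the deviation) trades a
small amount of long-range repulsion for roughly linear pair counts; with it
a 1,000-term layout takes ~3 s and a 4,000-term layout ~40–50 s on one CPU.
Forces are accumulated with `np.bincount` over the KD-tree pair list. If a
step produces non-finite coordinates the step size is halved and retried (at
most 5 times before a hard error); this path is defensive and not reached at
the defaults.

### Pins

A `PinConfig` maps terms to fixed `(x, y, z)`. Keys may be CURIEs
(`BFO:0000001`), expanded against the OBO PURL pattern at resolve time;
unresolved pins produce warnings, not errors. Pinned nodes contribute
repulsion and spring anchors but receive zero displacement, so pin fidelity
is exact by construction. `scaffold_fixture()` provides a 34-term,
four-stratum upper scaffold with a continuant-like pole at negative x and an
occurrent-like pole at positive x, pinned on exact tiers.

### Slice layout

`slice_layout(graph, scaffold_depth)` keeps depth ≤ `scaffold_depth` in the
3D force layout; each anchor's deeper subtree is drawn as a 2D tidy tree
(leaves spaced `jitter_radius` apart, parents centered over their extreme
children) embedded in the vertical half-plane through the anchor's azimuth.
This trades 3D structure for label separability on medium ontologies.

## 4. Scenes, hashing and cache

A scene is a JSON document (`schema_version` 1) with nodes (IRI, label,
position, color, size, flags), edges (colored by the child's prefix, with
thickness `max(1, 6 − parent_depth)`), the legend, and metadata.
`structure_hash` is the sha256 of the sorted node IRIs and sorted edges
*only* — labels and annotations are excluded, so relabeling does not
invalidate cached coordinates, while adding/removing any class or edge does.
The cache key combines `structure_hash`, the parameter digest, and the pin
set; a corrupt cache entry is treated as a miss with a warning. Scenes can
also be exported as GraphML (via networkx) for external tools.

## 5. Styling

A built-in table maps 37 well-known OBO prefixes to fixed colors, with
BFO-style upper-level terms in bright yellow `(255, 255, 0)`. Unknown
prefixes get a deterministic color by hashing the prefix to a hue
(sha256 → hue → HSV with fixed saturation/value), so arbitrary ontologies
are still consistently colored. Node sizes are 8 (top-level) and 3
(everything else); wireframe mode thins all non-scaffold edges. The legend
lists prefixes by descending term count, ties alphabetical.

## 6. Search and cross-references

Search is case-insensitive substring matching over labels and synonyms,
ranked label-prefix > label-substring > synonym match, ties in label order.
`term_context` returns label, definition, synonyms, drawn parent, children,
suppressed parents, and two lookup URLs: OntoBee (prefix + unmodified IRI)
and OLS4 (lowercased prefix + the IRI percent-encoded **twice**, which is
how the OLS4 path scheme expects embedded IRIs).

## 7. Synthetic fixture generator

`generate_ontology(FixtureSpec)` grows a tree level by level with a mean
branching factor, assigns terms round-robin-by-subtree to `n_prefixes` OBO
style prefixes, then adds exact counts of extra superclass axioms
(multi-parent fraction), deprecated terms (leaves only, so filtering never
forces re-parenting unless requested), and synonyms. Infeasible
combinations raise `ValueError`. `to_owl_xml` serializes with a
hand-written, byte-deterministic RDF/XML writer so generated files are
stable across runs and platforms. With `scaffold=True`, generated roots
attach beneath the pinned upper scaffold's leaf terms.

The generator emulates the *structural* properties that drive layout,
filtering and styling: depth distribution, branching, multiple inheritance,
deprecation, multi-ontology prefix mixing, synonymy. It does **not**
emulate OWL logical content (restrictions, equivalence axioms, imports
closure, punning) or realistic label text; conclusions about those must
come from real ontologies (the network-dependent tests fetch live OBO
files when a connection exists).

## 8. Limitations

- Only `rdfs:subClassOf` between named classes is visualized; other axiom
  types are ignored rather than summarized.
- The first-listed-parent rule is faithful to document order, but document
  order is an editorial artifact; two serializations of the same ontology
  can yield different trees (by design — determinism is per-document).
- The force model is heuristic: it guarantees stratification, determinism
  and pin fidelity, not optimality of any aesthetic criterion.
- Layout cost grows superlinearly with the largest generation; ontologies
  with hundreds of thousands of terms should be pruned by depth
  (`prune_depth` / `--max-depth`) first.
- The HTML viewer is a minimal self-contained canvas renderer intended for
  inspection, not a full visualization client.
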