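"""Scene assembly, serialization, and the layout coordinate cache.

A Scene is the fully positioned and styled node/edge set, ready for a viewer
or for caching.  The cache is keyed by a hash of the *class structure* alone
(sorted IRIs + sorted child/parent edges — labels, synonyms and colors are
excluded), so relabeling an ontology reuses the cached coordinates while any
structural edit invalidates them.  Because the layout is deterministic,
cached coordinates are exactly what a fresh simulation would produce.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .hierarchy import OntologyGraph
from .layout import Coordinates, LayoutParams, PinConfig, layout
from .styling import (
    ColorTable,
    DEFAULT_COLOR_TABLE,
    LegendEntry,
    build_legend,
    color_for_prefix,
    edge_thickness,
    node_size,
)

__all__ = [
    "Scene",
    "SceneNode",
    "SceneEdge",
    "SceneValidationError",
    "CacheRecord",
    "structure_hash",
    "build_scene",
    "write_scene",
    "read_scene",
    "load_or_layout",
    "write_graphml",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class SceneValidationError(ValueError):
    """A scene file violated the documented schema."""


@dataclass
class SceneNode:
    iri: str
    label: Optional[str]
    prefix: str
    depth: int
    deprecated: bool
    position: tuple[float, float, float]
    color: tuple[int, int, int]
    size: float
    pinned: bool


@dataclass
class SceneEdge:
    child_iri: str
    parent_iri: str
    thickness: int
    color: tuple[int, int, int]


@dataclass
class Scene:
    nodes: list[SceneNode]
    edges: list[SceneEdge]
    legend: list[LegendEntry]
    meta: dict

    def node_by_iri(self, iri: str) -> SceneNode:
        for n in self.nodes:
            if n.iri == iri:
                return n
        raise KeyError(iri)


def structure_hash(graph: OntologyGraph) -> str:
    """Digest of the class structure only: sorted IRIs + sorted edges."""
    payload = json.dumps(
        {"nodes": sorted(graph.nodes), "edges": sorted(graph.edges)},
        separators=(",", ":"),
    )
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def build_scene(
    graph: OntologyGraph,
    coords: Coordinates,
    table: ColorTable = DEFAULT_COLOR_TABLE,
    params: Optional[LayoutParams] = None,
    source_identifier: str = "",
    wireframe: bool = False,
) -> Scene:
    """Combine positioned graph + styling into a serializable Scene.

    Edges take the child node's color; scaffold edges (child pinned) keep
    default thickness even in wireframe mode.  Top-level emphasis (larger
    size) applies to pinned nodes and roots.
    """
    params = params or LayoutParams()
    nodes: list[SceneNode] = []
    for iri in sorted(graph.nodes):
        n = graph.nodes[iri]
        top = n.pinned or n.depth == 0
        nodes.append(
            SceneNode(
                iri=iri,
                label=n.label,
                prefix=n.prefix,
                depth=n.depth,
                deprecated=n.deprecated,
                position=tuple(coords[iri]),
                color=color_for_prefix(n.prefix, table),
                size=node_size(n.depth, top),
                pinned=n.pinned,
            )
        )
    edges: list[SceneEdge] = []
    for child, parent in sorted(graph.edges):
        scaffold = graph.nodes[child].pinned
        edges.append(
            SceneEdge(
                child_iri=child,
                parent_iri=parent,
                thickness=edge_thickness(
                    graph.nodes[parent].depth, wireframe=wireframe, scaffold=scaffold
                ),
                color=color_for_prefix(graph.nodes[child].prefix, table),
            )
        )
    meta = {
        "source_identifier": source_identifier,
        "structure_hash": structure_hash(graph),
        "params_digest": params.digest(),
        "creation_timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "tool_version": __version__,
    }
    return Scene(nodes=nodes, edges=edges, legend=build_legend(graph, table), meta=meta)


def _scene_to_dict(scene: Scene) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "nodes": [asdict(n) for n in scene.nodes],
        "edges": [asdict(e) for e in scene.edges],
        "legend": [asdict(e) for e in scene.legend],
        "meta": scene.meta,
    }


_NODE_FIELDS = ("iri", "label", "prefix", "depth", "deprecated",
                "position", "color", "size", "pinned")
_EDGE_FIELDS = ("child_iri", "parent_iri", "thickness", "color")


def write_scene(scene: Scene, path: str | Path) -> Path:
    """Serialize a scene losslessly to JSON (full float precision)."""
    path = Path(path)
    path.write_text(json.dumps(_scene_to_dict(scene), indent=1))
    return path


def read_scene(path: str | Path) -> Scene:
    """Load and validate a scene file; raises SceneValidationError on defects."""
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SceneValidationError(f"unreadable scene file {path}: {exc}") from exc
    if not isinstance(raw, dict) or raw.get("schema_version") != SCHEMA_VERSION:
        raise SceneValidationError(
            f"scene file {path}: missing or unsupported schema_version "
            f"(expected {SCHEMA_VERSION})"
        )
    for section in ("nodes", "edges", "legend", "meta"):
        if section not in raw:
            raise SceneValidationError(f"scene file {path}: missing field {section!r}")
    nodes = []
    iris = set()
    for rec in raw["nodes"]:
        for f in _NODE_FIELDS:
            if f not in rec:
                raise SceneValidationError(f"scene node missing field {f!r}")
        rec = dict(rec)
        rec["position"] = tuple(rec["position"])
        rec["color"] = tuple(rec["color"])
        nodes.append(SceneNode(**rec))
        iris.add(rec["iri"])
    edges = []
    for rec in raw["edges"]:
        for f in _EDGE_FIELDS:
            if f not in rec:
                raise SceneValidationError(f"scene edge missing field {f!r}")
        if rec["child_iri"] not in iris or rec["parent_iri"] not in iris:
            raise SceneValidationError(
                f"scene edge endpoint not among nodes: {rec['child_iri']} -> {rec['parent_iri']}"
            )
        rec = dict(rec)
        rec["color"] = tuple(rec["color"])
        edges.append(SceneEdge(**rec))
    legend = [
        LegendEntry(prefix=r["prefix"], color=tuple(r["color"]), term_count=r["term_count"])
        for r in raw["legend"]
    ]
    return Scene(nodes=nodes, edges=edges, legend=legend, meta=raw["meta"])


@dataclass
class CacheRecord:
    structure_hash: str
    params_digest: str
    coordinates: Coordinates = field(default_factory=dict)


def _cache_path(cache_dir: Path, digest: str) -> Path:
    return cache_dir / f"{digest}.json"


def load_or_layout(
    graph: OntologyGraph,
    pins: Optional[PinConfig] = None,
    params: Optional[LayoutParams] = None,
    cache_dir: Optional[str | Path] = None,
) -> tuple[Coordinates, bool]:
    """Return coordinates, reusing a cached layout when structure and
    parameters both match.

    Returns ``(coordinates, cache_hit)``.  A corrupt cache entry is treated
    as a miss and overwritten.
    """
    params = params or LayoutParams()
    if cache_dir is None:
        return layout(graph, pins, params), False
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    digest = structure_hash(graph)
    pdigest = params.digest()
    if pins is not None:
        pdigest = hashlib.sha256(
            (pdigest + json.dumps(sorted(pins.entries.items()))).encode()
        ).hexdigest()
    path = _cache_path(cache_dir, digest)
    if path.exists():
        try:
            raw = json.loads(path.read_text())
            if raw["params_digest"] == pdigest and raw["structure_hash"] == digest:
                coords = {iri: tuple(xyz) for iri, xyz in raw["coordinates"].items()}
                if set(coords) == set(graph.nodes):
                    logger.info("layout cache hit (%s)", digest[:12])
                    # pinned flags are normally set during layout; restore them
                    if pins is not None:
                        for iri in pins.resolve(graph):
                            graph.nodes[iri].pinned = True
                    return coords, True
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            logger.warning("corrupt layout cache entry %s (%s); recomputing", path, exc)
    logger.info("layout cache miss (%s)", digest[:12])
    coords = layout(graph, pins, params)
    record = {
        "structure_hash": digest,
        "params_digest": pdigest,
        "coordinates": {iri: list(xyz) for iri, xyz in coords.items()},
    }
    path.write_text(json.dumps(record))
    return coords, False


def write_graphml(scene: Scene, path: str | Path) -> Path:
    """Export nodes + edges with positions for third-party graph viewers."""
    import networkx as nx

    g = nx.DiGraph()
    for n in scene.nodes:
        g.add_node(
            n.iri,
            label=n.label or "",
            prefix=n.prefix,
            depth=n.depth,
            x=n.position[0],
            y=n.position[1],
            z=n.position[2],
        )
    for e in scene.edges:
        g.add_edge(e.child_iri, e.parent_iri, thickness=e.thickness)
    nx.write_graphml(g, str(path))
    return Path(path)
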