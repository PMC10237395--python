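"""Node colors, sizes, edge thickness, and the per-prefix legend.

Every node of a given ontology prefix receives one fixed color, so imported
terms are recognizable at a glance.  The shipped table covers the common OBO
Foundry prefixes; unknown prefixes get a deterministic hue-hashed fallback.
Upper-ontology scaffold terms are bright yellow and oversized so they stay
visible when zoomed far out.
"""

from __future__ import annotations

import colorsys
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from .hierarchy import OntologyGraph

__all__ = [
    "ColorTable",
    "LegendEntry",
    "DEFAULT_COLOR_TABLE",
    "color_for_prefix",
    "edge_thickness",
    "node_size",
    "build_legend",
]

RGB = tuple[int, int, int]

SCAFFOLD_YELLOW: RGB = (255, 255, 0)

#: Curated palette for common OBO Foundry prefixes.  The upper-level
#: ontology (BFO, and this project's synthetic UPPER scaffold) is bright
#: yellow by design.
_DEFAULT_ENTRIES: dict[str, RGB] = {
    "BFO": SCAFFOLD_YELLOW,
    "UPPER": SCAFFOLD_YELLOW,
    "OBI": (255, 255, 255),
    "PATO": (64, 192, 64),
    "GO": (255, 140, 0),
    "CL": (60, 120, 255),
    "CHEBI": (170, 110, 40),
    "DOID": (220, 60, 60),
    "UBERON": (240, 100, 200),
    "ENVO": (40, 160, 120),
    "NCBITAXON": (130, 130, 200),
    "PR": (150, 80, 200),
    "SO": (200, 180, 60),
    "IAO": (120, 200, 220),
    "OBA": (100, 60, 160),
    "HP": (90, 50, 110),
    "MP": (160, 110, 170),
    "MONDO": (200, 90, 30),
    "FOODON": (110, 170, 40),
    "AGRO": (80, 140, 60),
    "GENEPIO": (230, 130, 130),
    "RO": (150, 150, 150),
    "UO": (200, 200, 120),
    "PO": (50, 180, 80),
    "TO": (140, 190, 90),
    "ECO": (70, 100, 180),
    "NCIT": (180, 60, 120),
    "OGMS": (220, 170, 40),
    "OMRSE": (110, 110, 60),
    "MAXO": (60, 200, 200),
    "SYMP": (250, 180, 110),
    "IDO": (160, 40, 70),
    "CIDO": (90, 160, 250),
    "TRANS": (210, 110, 250),
    "FMA": (250, 220, 160),
    "CARO": (100, 200, 160),
    "owl": (255, 255, 0),  # owl:Thing root, part of the yellow summit
}


def _hash_fallback(prefix: str) -> RGB:
    """Deterministic hue-hashed color for prefixes outside the table.

    Hash collisions between unknown prefixes are possible (1/256 hue bins);
    colors are stable across runs and platforms.
    """
    digest = hashlib.sha256(prefix.encode("utf-8")).digest()
    hue = digest[0] / 255.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.6, 0.9)
    return (int(r * 255), int(g * 255), int(b * 255))


@dataclass
class ColorTable:
    entries: dict[str, RGB] = field(default_factory=dict)
    fallback_rule: Callable[[str], RGB] = _hash_fallback

    @classmethod
    def from_json(cls, path: str | Path) -> "ColorTable":
        """Load ``{PREFIX: "#RRGGBB"}`` from a JSON file."""
        raw = json.loads(Path(path).read_text())
        entries = {}
        for prefix, hexcolor in raw.items():
            h = hexcolor.lstrip("#")
            entries[prefix] = (int(h[0:2], 16), int(h[2:4], 16), int(h[4:6], 16))
        return cls(entries=entries)


DEFAULT_COLOR_TABLE = ColorTable(entries=dict(_DEFAULT_ENTRIES))


def color_for_prefix(prefix: str, table: ColorTable = DEFAULT_COLOR_TABLE) -> RGB:
    """Table color when present, else the deterministic fallback."""
    if prefix in table.entries:
        return table.entries[prefix]
    return table.fallback_rule(prefix)


#: depth-0 edge thickness in default mode; thinner by one unit per level
EDGE_T0 = 6
NODE_SIZE_TOP = 8.0
NODE_SIZE_BASE = 3.0


def edge_thickness(depth_of_parent: int, wireframe: bool = False,
                   scaffold: bool = False, t0: int = EDGE_T0) -> int:
    """Edge thickness: heavier near the summit, 1 unit past depth t0-1.

    Wireframe mode flattens every non-scaffold edge to the cheapest 1-unit
    line; scaffold (upper-ontology) edges keep their default thickness.
    """
    if depth_of_parent < 0:
        raise ValueError("depth must be non-negative")
    default = max(1, t0 - depth_of_parent)
    if wireframe and not scaffold:
        return 1
    return default


def node_size(depth: int, is_top_level: bool,
              s_top: float = NODE_SIZE_TOP, s_base: float = NODE_SIZE_BASE) -> float:
    """Top-level (scaffold/root) nodes are oversized; everything else uniform."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    return s_top if is_top_level else s_base


@dataclass
class LegendEntry:
    prefix: str
    color: RGB
    term_count: int


def build_legend(graph: OntologyGraph,
                 table: ColorTable = DEFAULT_COLOR_TABLE) -> list[LegendEntry]:
    """One entry per prefix, descending count, ties alphabetical.

    Counts partition the node set: their sum equals the number of nodes.
    """
    counts: dict[str, int] = {}
    for node in graph.nodes.values():
        counts[node.prefix] = counts.get(node.prefix, 0) + 1
    entries = [
        LegendEntry(prefix=p, color=color_for_prefix(p, table), term_count=c)
        for p, c in counts.items()
    ]
    entries.sort(key=lambda e: (-e.term_count, e.prefix))
    return entries
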