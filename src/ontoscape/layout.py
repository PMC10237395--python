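"""Deterministic depth-stratified 3D layout.

Every node sits on the horizontal plane of its hierarchy depth
(``y = -depth * tier_spacing``); the force simulation only ever moves nodes
in the x-z plane.  Nodes named in a :class:`PinConfig` (typically an
upper-ontology scaffold) never move at all, so the summit of the term
landscape keeps a recognizable constellation across reloads and even across
edits to the underlying ontology.

Children are inserted generation by generation: each depth stratum is spawned
pseudo-randomly around its parents only after the previous stratum has
settled.  This top-down "mountain building" avoids the ostracised nodes that
all-at-once random initialization traps far from their neighbours.  All
randomness is derived by hashing a master seed with each node's IRI, so two
runs over the same class structure are bitwise identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .hierarchy import OntologyGraph, prune_depth

__all__ = [
    "PinConfig",
    "LayoutParams",
    "LayoutStats",
    "derive_seed",
    "spawn_position",
    "layout",
    "layout_all_at_once",
    "slice_layout",
    "tidy_tree_2d",
    "median_parent_distance",
]

logger = logging.getLogger(__name__)

Coordinates = dict[str, tuple[float, float, float]]

_OBO_PURL = "http://purl.obolibrary.org/obo/"


@dataclass
class PinConfig:
    """Fixed 3D coordinates for scaffold terms, keyed by CURIE or IRI."""

    entries: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "PinConfig":
        raw = json.loads(Path(path).read_text())
        entries = {}
        for key, xyz in raw.items():
            x, y, z = (float(v) for v in xyz)
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise ValueError(f"non-finite pinned coordinate for {key!r}")
            entries[key] = (x, y, z)
        return cls(entries=entries)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({k: list(v) for k, v in self.entries.items()}, indent=1)
        )

    def resolve(self, graph: OntologyGraph) -> dict[str, tuple[float, float, float]]:
        """Map entries onto graph IRIs; CURIEs expand as OBO PURLs.

        Unresolved entries are ignored with a warning.
        """
        resolved: dict[str, tuple[float, float, float]] = {}
        for key, xyz in self.entries.items():
            iri = key
            if iri not in graph.nodes and ":" in key and "://" not in key:
                prefix, local = key.split(":", 1)
                iri = f"{_OBO_PURL}{prefix}_{local}"
            if iri in graph.nodes:
                resolved[iri] = xyz
            else:
                logger.warning("pinned term %s not present in graph; ignored", key)
        return resolved


@dataclass(frozen=True)
class LayoutParams:
    """Force and stratum constants.

    Units are scene units throughout; one depth stratum spans
    ``tier_spacing`` units vertically.
    """

    tier_spacing: float = 100.0
    repulsion_k: float = 500.0        # inverse-square repulsion constant
    spring_k: float = 0.1             # attraction toward parent, per unit offset
    damping: float = 0.6              # velocity decay per step, in (0, 1)
    max_iter_per_generation: int = 300
    settle_epsilon: float = 0.1       # max per-step displacement to declare settled
    jitter_radius: float = 30.0       # child spawn offset radius
    master_seed: int = 1
    repulsion_cutoff_factor: float = 1.5  # cutoff = factor * tier_spacing
    generation_cooling: float = 0.3   # temperature multiplier per elapsed generation
    iteration_cooling: float = 0.97   # annealing factor per relaxation step
    max_step: float = 25.0            # per-node displacement clamp per iteration
    min_separation: float = 2.0       # distance floor for the repulsion kernel

    def __post_init__(self):
        if not (0.0 < self.damping < 1.0):
            raise ValueError("damping must be strictly between 0 and 1")
        for name in ("tier_spacing", "repulsion_k", "spring_k", "settle_epsilon",
                     "jitter_radius", "repulsion_cutoff_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class LayoutStats:
    total_iterations: int = 0
    iterations_per_generation: list[int] = field(default_factory=list)


def derive_seed(master_seed: int, iri: str) -> int:
    """Stable 64-bit seed mixing the master seed with a hash of the IRI."""
    h = hashlib.sha256(str(int(master_seed)).encode() + b"\x00" + iri.encode("utf-8"))
    return int.from_bytes(h.digest()[:8], "big")


def spawn_position(
    parent_xz: tuple[float, float], node_seed: int, jitter_radius: float
) -> tuple[float, float]:
    """Parent position plus a seed-determined planar offset.

    Offset magnitude lies in ``[0.2 * jitter_radius, jitter_radius]`` so two
    siblings can never coincide with their parent (or, in practice, with each
    other — distinct seeds give distinct angles).
    """
    if jitter_radius <= 0:
        raise ValueError("jitter_radius must be positive")
    u1 = (node_seed & 0xFFFFFFFF) / 2**32
    u2 = ((node_seed >> 32) & 0xFFFFFFFF) / 2**32
    angle = 2.0 * math.pi * u1
    radius = jitter_radius * (0.2 + 0.8 * u2)
    return (
        parent_xz[0] + radius * math.cos(angle),
        parent_xz[1] + radius * math.sin(angle),
    )


class _Simulation:
    """Planar force relaxation over a growing active node set."""

    def __init__(self, iris: list[str], params: LayoutParams):
        n = len(iris)
        self.iris = iris
        self.index = {iri: i for i, iri in enumerate(iris)}
        self.params = params
        self.pos = np.zeros((n, 2))          # x, z
        self.vel = np.zeros((n, 2))
        self.active = np.zeros(n, dtype=bool)
        self.pinned = np.zeros(n, dtype=bool)
        self.birth_gen = np.zeros(n, dtype=int)
        self.parent_idx = np.full(n, -1, dtype=int)
        self.cutoff = params.repulsion_cutoff_factor * params.tier_spacing

    def _forces(self) -> np.ndarray:
        p = self.params
        act = np.flatnonzero(self.active)
        forces = np.zeros_like(self.pos)
        # spring toward parent (only where the parent is active)
        has_parent = act[self.parent_idx[act] >= 0]
        if has_parent.size:
            par = self.parent_idx[has_parent]
            live = self.active[par]
            child = has_parent[live]
            par = par[live]
            forces[child] += p.spring_k * (self.pos[par] - self.pos[child])
        # pairwise inverse-square repulsion with cutoff (pinned nodes repel
        # but are never moved)
        pts = self.pos[act]
        if act.size > 1:
            pairs = cKDTree(pts).query_pairs(r=self.cutoff, output_type="ndarray")
            if pairs.size:
                i, j = act[pairs[:, 0]], act[pairs[:, 1]]
                d = self.pos[i] - self.pos[j]
                dist = np.linalg.norm(d, axis=1)
                dist = np.maximum(dist, p.min_separation)
                f = (p.repulsion_k / dist**3)[:, None] * d
                n = len(self.pos)
                forces[:, 0] += np.bincount(i, weights=f[:, 0], minlength=n)
                forces[:, 1] += np.bincount(i, weights=f[:, 1], minlength=n)
                forces[:, 0] -= np.bincount(j, weights=f[:, 0], minlength=n)
                forces[:, 1] -= np.bincount(j, weights=f[:, 1], minlength=n)
        return forces

    def relax(self, current_gen: int, max_iter: int) -> int:
        """Step until settled or max_iter; returns iterations run."""
        p = self.params
        movable = self.active & ~self.pinned
        if not movable.any():
            return 0
        temp = np.where(
            movable,
            p.generation_cooling ** np.maximum(current_gen - self.birth_gen, 0),
            0.0,
        )[:, None]
        step_scale = 1.0
        halvings = 0
        it = 0
        anneal = 1.0
        while it < max_iter:
            prev_pos = self.pos.copy()
            prev_vel = self.vel.copy()
            forces = self._forces()
            self.vel = (self.vel + forces * step_scale) * p.damping
            # clamp per-step travel: keeps tight spawn clusters from
            # launching each other into oscillation
            speed = np.linalg.norm(self.vel, axis=1)
            over = speed > p.max_step
            if over.any():
                self.vel[over] *= (p.max_step / speed[over])[:, None]
            disp = self.vel * temp * anneal
            anneal *= p.iteration_cooling
            self.pos = self.pos + np.where(movable[:, None], disp, 0.0)
            it += 1
            if not np.isfinite(self.pos).all():
                self.pos, self.vel = prev_pos, prev_vel
                step_scale *= 0.5
                halvings += 1
                if halvings > 5:
                    raise RuntimeError("force layout diverged despite step halving")
                continue
            if np.abs(disp[movable]).max(initial=0.0) < p.settle_epsilon:
                break
        return it


def _prepare(graph: OntologyGraph, pins: Optional[PinConfig], params: LayoutParams):
    iris = sorted(graph.nodes)
    sim = _Simulation(iris, params)
    resolved = pins.resolve(graph) if pins is not None else {}
    depth = np.array([graph.nodes[i].depth for i in iris], dtype=int)
    for iri, n in graph.nodes.items():
        idx = sim.index[iri]
        if n.parent is not None and n.parent in sim.index:
            sim.parent_idx[idx] = sim.index[n.parent]
        if iri in resolved:
            sim.pinned[idx] = True
            graph.nodes[iri].pinned = True
    return sim, resolved, depth


def _place_roots(sim: _Simulation, resolved, iris: list[str], depth: np.ndarray,
                 params: LayoutParams) -> None:
    root_idx = [i for i in range(len(iris)) if depth[i] == 0]
    unpinned_roots = [i for i in root_idx if not sim.pinned[i]]  # already IRI-sorted
    m = len(unpinned_roots)
    for k, i in enumerate(unpinned_roots):
        ang = 2.0 * math.pi * k / m
        sim.pos[i] = (params.tier_spacing * math.cos(ang),
                      params.tier_spacing * math.sin(ang))
    for i in root_idx:
        if sim.pinned[i]:
            x, _, z = resolved[iris[i]]
            sim.pos[i] = (x, z)
        sim.active[i] = True
        sim.birth_gen[i] = 0


def _assemble(sim: _Simulation, resolved, iris, depth, params) -> Coordinates:
    coords: Coordinates = {}
    for i, iri in enumerate(iris):
        if iri in resolved:
            coords[iri] = resolved[iri]
        else:
            coords[iri] = (
                float(sim.pos[i, 0]),
                float(-depth[i] * params.tier_spacing),
                float(sim.pos[i, 1]),
            )
    return coords


def layout(
    graph: OntologyGraph,
    pins: Optional[PinConfig] = None,
    params: Optional[LayoutParams] = None,
    stats: Optional[LayoutStats] = None,
) -> Coordinates:
    """Generational-insertion force layout.

    Depth-0 nodes are placed first (pinned ones exactly at their pins, the
    rest evenly on a circle of radius ``tier_spacing``, in IRI order); each
    subsequent generation spawns near its parents, then the planar forces
    relax until the largest per-step displacement drops below
    ``settle_epsilon``.  Earlier generations stay mobile with an
    exponentially decaying temperature.  Deterministic: identical inputs give
    bitwise-identical coordinates.
    """
    if not graph.nodes:
        raise ValueError("cannot lay out an empty graph")
    params = params or LayoutParams()
    sim, resolved, depth = _prepare(graph, pins, params)
    iris = sim.iris
    _place_roots(sim, resolved, iris, depth, params)

    max_d = int(depth.max(initial=0))
    it0 = sim.relax(0, params.max_iter_per_generation)
    if stats is not None:
        stats.iterations_per_generation.append(it0)
        stats.total_iterations += it0
    for g in range(1, max_d + 1):
        for i in np.flatnonzero(depth == g):
            iri = iris[i]
            if sim.pinned[i]:
                x, _, z = resolved[iri]
                sim.pos[i] = (x, z)
            else:
                pidx = sim.parent_idx[i]
                parent_xz = tuple(sim.pos[pidx]) if pidx >= 0 else (0.0, 0.0)
                sim.pos[i] = spawn_position(
                    parent_xz, derive_seed(params.master_seed, iri), params.jitter_radius
                )
            sim.active[i] = True
            sim.birth_gen[i] = g
        it = sim.relax(g, params.max_iter_per_generation)
        if stats is not None:
            stats.iterations_per_generation.append(it)
            stats.total_iterations += it
    return _assemble(sim, resolved, iris, depth, params)


def layout_all_at_once(
    graph: OntologyGraph,
    pins: Optional[PinConfig] = None,
    params: Optional[LayoutParams] = None,
    iteration_budget: Optional[int] = None,
) -> Coordinates:
    """Baseline layout: every node starts at a random planar position.

    All nodes are activated immediately, initialized uniformly in a disc of
    radius ``repulsion_cutoff_factor * tier_spacing``, and relaxed for
    ``iteration_budget`` steps.  Exists to quantify what generational
    insertion buys: with equal budgets it leaves nodes stranded far from
    their parents ("ostracised" nodes).
    """
    if not graph.nodes:
        raise ValueError("cannot lay out an empty graph")
    params = params or LayoutParams()
    sim, resolved, depth = _prepare(graph, pins, params)
    iris = sim.iris
    disc_r = params.repulsion_cutoff_factor * params.tier_spacing
    for i, iri in enumerate(iris):
        if sim.pinned[i]:
            x, _, z = resolved[iri]
            sim.pos[i] = (x, z)
        else:
            s = derive_seed(params.master_seed, iri)
            u1 = (s & 0xFFFFFFFF) / 2**32
            u2 = ((s >> 32) & 0xFFFFFFFF) / 2**32
            ang = 2.0 * math.pi * u1
            r = disc_r * math.sqrt(u2)
            sim.pos[i] = (r * math.cos(ang), r * math.sin(ang))
        sim.active[i] = True
        sim.birth_gen[i] = 0
    if iteration_budget is None:
        iteration_budget = params.max_iter_per_generation * (int(depth.max(initial=0)) + 1)
    sim.relax(0, iteration_budget)  # stops early only if fully settled
    return _assemble(sim, resolved, iris, depth, params)


def median_parent_distance(graph: OntologyGraph, coords: Coordinates) -> float:
    """Median planar (x-z) child-parent distance over all edges."""
    dists = []
    for child, parent in graph.edges:
        cx, _, cz = coords[child]
        px, _, pz = coords[parent]
        dists.append(math.hypot(cx - px, cz - pz))
    return float(np.median(dists)) if dists else 0.0


def tidy_tree_2d(
    fragment: OntologyGraph, params: Optional[LayoutParams] = None
) -> dict[str, tuple[float, float]]:
    """Layered tidy layout of a single tree in a 2D half-plane.

    ``v = -relative_depth * tier_spacing``; siblings are ordered by IRI and
    occupy disjoint horizontal intervals; each parent is centered over its
    children; the root sits at ``u = 0``.
    """
    params = params or LayoutParams()
    if len(fragment.roots) != 1:
        raise ValueError("tidy_tree_2d requires a single-root tree fragment")
    root = fragment.roots[0]
    children: dict[str, list[str]] = {}
    for c, p in fragment.edges:
        children.setdefault(p, []).append(c)
    for kids in children.values():
        kids.sort()
    leaf_w = params.jitter_radius

    width: dict[str, float] = {}

    def measure(iri: str) -> float:
        kids = children.get(iri, [])
        width[iri] = sum(measure(k) for k in kids) if kids else leaf_w
        return width[iri]

    measure(root)
    uv: dict[str, tuple[float, float]] = {}

    def place(iri: str, left: float, rel_depth: int) -> None:
        kids = children.get(iri, [])
        v = -rel_depth * params.tier_spacing
        if not kids:
            uv[iri] = (left + width[iri] / 2.0, v)
            return
        cursor = left
        for k in kids:
            place(k, cursor, rel_depth + 1)
            cursor += width[k]
        first_u = uv[kids[0]][0]
        last_u = uv[kids[-1]][0]
        uv[iri] = ((first_u + last_u) / 2.0, v)

    place(root, -width[root] / 2.0, 0)
    shift = uv[root][0]
    return {iri: (u - shift, v) for iri, (u, v) in uv.items()}


def slice_layout(
    graph: OntologyGraph,
    pins: Optional[PinConfig] = None,
    params: Optional[LayoutParams] = None,
    scaffold_depth: int = 2,
) -> Coordinates:
    """Hybrid view: 3D layout above ``scaffold_depth``, 2D slices below.

    Nodes at depth <= scaffold_depth are positioned by :func:`layout` on the
    pruned upper graph.  Each deeper node belongs to the subtree of its
    ancestor at exactly ``scaffold_depth``; that subtree is laid out by
    :func:`tidy_tree_2d` in the vertical half-plane through its anchor, with
    azimuth equal to the anchor's azimuth about the scene's vertical axis.
    """
    if scaffold_depth < 0:
        raise ValueError("scaffold_depth must be non-negative")
    params = params or LayoutParams()
    upper = prune_depth(graph, scaffold_depth)
    coords = layout(upper, pins, params)
    if graph.max_depth() <= scaffold_depth:
        return coords

    # anchor of each deep node = its ancestor at depth scaffold_depth
    anchor_of: dict[str, str] = {}
    for iri, node in sorted(graph.nodes.items()):
        if node.depth <= scaffold_depth:
            continue
        cur = iri
        while cur is not None and graph.nodes[cur].depth > scaffold_depth:
            cur = graph.nodes[cur].parent
        if cur is not None:
            anchor_of[iri] = cur

    by_anchor: dict[str, list[str]] = {}
    for iri, anchor in anchor_of.items():
        by_anchor.setdefault(anchor, []).append(iri)

    for anchor in sorted(by_anchor):
        members = by_anchor[anchor]
        sub_nodes = {anchor: graph.nodes[anchor]}
        sub_nodes.update({m: graph.nodes[m] for m in members})
        sub_edges = [
            (c, p) for c, p in graph.edges if c in sub_nodes and p in sub_nodes
        ]
        fragment = OntologyGraph(
            nodes=sub_nodes, edges=sub_edges, roots=[anchor], standalone_roots=[]
        )
        uv = tidy_tree_2d(fragment, params)
        ax, ay, az = coords[anchor]
        norm = math.hypot(ax, az)
        if norm < 1e-9:
            dx, dz = 1.0, 0.0
        else:
            dx, dz = ax / norm, az / norm
        for iri, (u, v) in uv.items():
            if iri == anchor:
                continue
            coords[iri] = (ax + u * dx, ay + v, az + u * dz)
    return coords
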