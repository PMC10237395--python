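"""Deterministic synthetic OBO-style ontologies for offline testing.

Generates multi-prefix class hierarchies with OBO-PURL IRIs, labels,
synonyms, deprecation flags and (optionally) second superclass axioms, and
serializes them as RDF/XML byte-identically for a given spec.  Also ships a
34-term two-pole upper-ontology scaffold with pinned coordinates, emulating
the continuant/occurrent poles of a BFO-like upper level without reproducing
any real ontology's IRIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional
from xml.sax.saxutils import escape, quoteattr

import numpy as np

from .ingest import RawTerm, RawTermSet
from .layout import PinConfig

__all__ = [
    "FixtureSpec",
    "generate_ontology",
    "scaffold_fixture",
    "to_owl_xml",
    "SCAFFOLD_PREFIX",
]

_OBO = "http://purl.obolibrary.org/obo/"

_PREFIX_POOL = [
    "OBI", "PATO", "GO", "CL", "CHEBI", "UBERON", "ENVO", "IAO", "SO", "DOID",
    "HP", "MP", "PR", "ECO", "UO", "PO", "TO", "NCIT", "FOODON", "AGRO",
    "MONDO", "SYMP", "IDO", "CIDO", "OGMS", "MAXO", "OBA", "CARO", "FMA", "TRANS",
]

SCAFFOLD_PREFIX = "UPPER"


@dataclass(frozen=True)
class FixtureSpec:
    """Shape parameters of one synthetic ontology."""

    n_terms: int = 100
    n_prefixes: int = 3
    branching_mean: float = 3.0
    multi_parent_fraction: float = 0.0
    deprecated_fraction: float = 0.0
    synonym_fraction: float = 0.0
    seed: int = 0
    #: hang the generated hierarchy beneath the 34-term pinned scaffold
    scaffold: bool = False

    def __post_init__(self):
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if self.branching_mean <= 0:
            raise ValueError("branching_mean must be positive")
        for f in ("multi_parent_fraction", "deprecated_fraction", "synonym_fraction"):
            if not (0.0 <= getattr(self, f) <= 1.0):
                raise ValueError(f"{f} must lie in [0, 1]")


def _prefixes(n: int) -> list[str]:
    if n <= len(_PREFIX_POOL):
        return _PREFIX_POOL[:n]
    extra = [f"OX{i}" for i in range(n - len(_PREFIX_POOL))]
    return _PREFIX_POOL + extra


def to_owl_xml(raw: RawTermSet) -> str:
    """RDF/XML serialization preserving superclass axiom order.

    Deterministic: iterates terms in insertion order and writes axioms in
    list order, so identical RawTermSets give identical bytes.
    """
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"',
        '         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"',
        '         xmlns:owl="http://www.w3.org/2002/07/owl#"',
        '         xmlns:oboInOwl="http://www.geneontology.org/formats/oboInOwl#"',
        '         xmlns:obo="http://purl.obolibrary.org/obo/">',
    ]
    for term in raw.terms.values():
        lines.append(f"  <owl:Class rdf:about={quoteattr(term.iri)}>")
        if term.label is not None:
            lines.append(
                f'    <rdfs:label xml:lang="en">{escape(term.label)}</rdfs:label>'
            )
        for sup in term.superclass_iris:
            lines.append(f"    <rdfs:subClassOf rdf:resource={quoteattr(sup)}/>")
        for syn in term.synonyms:
            lines.append(
                f"    <oboInOwl:hasExactSynonym>{escape(syn)}</oboInOwl:hasExactSynonym>"
            )
        if term.definition is not None:
            lines.append(f"    <obo:IAO_0000115>{escape(term.definition)}</obo:IAO_0000115>")
        if term.deprecated:
            lines.append(
                '    <owl:deprecated rdf:datatype='
                '"http://www.w3.org/2001/XMLSchema#boolean">true</owl:deprecated>'
            )
        lines.append("  </owl:Class>")
    lines.append("</rdf:RDF>")
    return "\n".join(lines) + "\n"


def generate_ontology(
    spec: FixtureSpec, path: Optional[str | Path] = None
) -> tuple[RawTermSet, str]:
    """Generate a synthetic ontology; returns (ground truth, OWL text).

    The hierarchy grows root-down level by level: each level is
    ``branching_mean`` times the previous one until ``n_terms`` classes
    exist.  Exactly ``round(multi_parent_fraction * (n_terms - 1))`` non-root
    terms get a second superclass axiom (serialized after the first);
    ``round(deprecated_fraction * n_terms)`` leaf terms are deprecated.
    Same spec (same seed) gives byte-identical OWL output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_terms
    prefixes = _prefixes(spec.n_prefixes)

    # level structure
    levels: list[list[int]] = [[0]]
    created = 1
    while created < n:
        prev = levels[-1]
        size = int(round(len(prev) * spec.branching_mean))
        size = min(size, n - created)
        if size < 1:
            raise ValueError(
                f"infeasible spec: branching_mean={spec.branching_mean} cannot "
                f"reach n_terms={n} (stalled at {created})"
            )
        levels.append(list(range(created, created + size)))
        created += size

    prefix_of = [prefixes[0]] + [
        prefixes[int(k)] for k in rng.integers(0, len(prefixes), size=n - 1)
    ]
    iris = [f"{_OBO}{prefix_of[i]}_{1000000 + i:07d}" for i in range(n)]

    parent = [-1] * n
    for lvl in range(1, len(levels)):
        prev = levels[lvl - 1]
        for i in levels[lvl]:
            parent[i] = prev[int(rng.integers(0, len(prev)))]

    # second superclass axioms: exact count, deterministic selection
    eligible = [i for i in range(1, n) if any(j != parent[i] for j in range(i))]
    k_multi = int(round(spec.multi_parent_fraction * (n - 1)))
    if k_multi > len(eligible):
        raise ValueError("infeasible spec: not enough terms for multi_parent_fraction")
    multi = sorted(rng.choice(eligible, size=k_multi, replace=False).tolist()) if k_multi else []
    second_parent: dict[int, int] = {}
    for i in multi:
        candidates = [j for j in range(i) if j != parent[i]]
        second_parent[i] = candidates[int(rng.integers(0, len(candidates)))]

    # deprecated terms: leaves only, so hiding them removes exactly this count
    has_child = set(p for p in parent if p >= 0)
    leaves = [i for i in range(n) if i not in has_child and i != 0]
    k_dep = int(round(spec.deprecated_fraction * n))
    if k_dep > len(leaves):
        raise ValueError(
            f"infeasible spec: {k_dep} deprecated terms requested but only "
            f"{len(leaves)} leaves available"
        )
    deprecated = set(
        rng.choice(leaves, size=k_dep, replace=False).tolist()
    ) if k_dep else set()

    k_syn = int(round(spec.synonym_fraction * n))
    with_syn = set(
        rng.choice(n, size=k_syn, replace=False).tolist()
    ) if k_syn else set()

    scaffold_terms: dict[str, RawTerm] = {}
    root_superclass: Optional[str] = None
    if spec.scaffold:
        _, scaffold_raw = scaffold_fixture()
        scaffold_terms = dict(scaffold_raw.terms)
        scaffold_leaves = [
            t.iri
            for t in scaffold_raw.terms.values()
            if not any(
                t.iri in o.superclass_iris for o in scaffold_raw.terms.values()
            )
        ]
        root_superclass = scaffold_leaves[int(rng.integers(0, len(scaffold_leaves)))]

    terms: dict[str, RawTerm] = dict(scaffold_terms)
    for i in range(n):
        sup: list[str] = []
        if parent[i] >= 0:
            sup.append(iris[parent[i]])
        elif root_superclass is not None:
            sup.append(root_superclass)
        if i in second_parent:
            sup.append(iris[second_parent[i]])
        label = f"{prefix_of[i].lower()} term {i:04d}"
        terms[iris[i]] = RawTerm(
            iri=iris[i],
            label=label,
            synonyms=[f"alt name {i:04d}"] if i in with_syn else [],
            definition=f"Synthetic class number {i} of a generated test ontology.",
            deprecated=i in deprecated,
            superclass_iris=sup,
        )

    source = str(path) if path else f"synthetic:seed={spec.seed},n={n}"
    raw = RawTermSet(terms=terms, source_identifier=source, format="rdfxml")
    owl_text = to_owl_xml(raw)
    if path is not None:
        Path(path).write_text(owl_text)
    return raw, owl_text


# ---------------------------------------------------------------------------
# 34-term upper-ontology scaffold with pinned coordinates
# ---------------------------------------------------------------------------

# (local id, label, parent local id or None); two poles under the root:
# continuant-like (negative x) and occurrent-like (positive x).
_SCAFFOLD_TERMS: list[tuple[int, str, Optional[int]]] = [
    (1, "entity", None),
    (2, "continuant", 1),
    (3, "occurrent", 1),
    (4, "independent continuant", 2),
    (5, "dependent continuant", 2),
    (6, "spatial region", 2),
    (7, "process", 3),
    (8, "temporal region", 3),
    (9, "spatiotemporal region", 3),
    (10, "process boundary", 7),
    (11, "material entity", 4),
    (12, "immaterial entity", 4),
    (13, "object", 11),
    (14, "fiat object part", 11),
    (15, "object aggregate", 11),
    (16, "site", 12),
    (17, "continuant fiat boundary", 12),
    (18, "zero-dimensional continuant fiat boundary", 17),
    (19, "one-dimensional continuant fiat boundary", 17),
    (20, "two-dimensional continuant fiat boundary", 17),
    (21, "generically dependent continuant", 5),
    (22, "specifically dependent continuant", 5),
    (23, "quality", 22),
    (24, "realizable entity", 22),
    (25, "role", 24),
    (26, "disposition", 24),
    (27, "function", 26),
    (28, "zero-dimensional spatial region", 6),
    (29, "one-dimensional spatial region", 6),
    (30, "two-dimensional spatial region", 6),
    (31, "three-dimensional spatial region", 6),
    (32, "zero-dimensional temporal region", 8),
    (33, "one-dimensional temporal region", 8),
    (34, "history", 7),
]

_CONTINUANT_POLE_ROOT = 2
_OCCURRENT_POLE_ROOT = 3
_TIER = 100.0


def _scaffold_iri(local: int) -> str:
    return f"{_OBO}{SCAFFOLD_PREFIX}_{local:07d}"


def scaffold_fixture() -> tuple[PinConfig, RawTermSet]:
    """34-term two-pole upper scaffold with pinned coordinates.

    The continuant-like pole occupies negative x, the occurrent-like pole
    positive x; every pin sits exactly on its depth stratum
    (``y = -depth * 100``).  Pin keys are CURIEs (``UPPER:0000002``).
    """
    parent_of = {local: par for local, _, par in _SCAFFOLD_TERMS}

    def depth(local: int) -> int:
        d = 0
        while parent_of[local] is not None:
            local = parent_of[local]
            d += 1
        return d

    def pole(local: int) -> int:
        # -1 continuant side, +1 occurrent side, 0 root
        while parent_of[local] is not None:
            if local == _CONTINUANT_POLE_ROOT:
                return -1
            if local == _OCCURRENT_POLE_ROOT:
                return +1
            local = parent_of[local]
        return 0

    # group terms by (pole, depth), spread each group along x
    groups: dict[tuple[int, int], list[int]] = {}
    for local, _, _ in _SCAFFOLD_TERMS:
        groups.setdefault((pole(local), depth(local)), []).append(local)

    pins: dict[str, tuple[float, float, float]] = {}
    for (side, d), members in sorted(groups.items()):
        members.sort()
        m = len(members)
        center_x = 220.0 * side
        for idx, local in enumerate(members):
            x = center_x + (idx - (m - 1) / 2.0) * 70.0
            z = ((idx % 3) - 1) * 45.0 + side * 20.0
            pins[f"{SCAFFOLD_PREFIX}:{local:07d}"] = (x, -d * _TIER, z)

    terms: dict[str, RawTerm] = {}
    for local, label, par in _SCAFFOLD_TERMS:
        terms[_scaffold_iri(local)] = RawTerm(
            iri=_scaffold_iri(local),
            label=label,
            definition=f"Upper-level scaffold class: {label}.",
            superclass_iris=[_scaffold_iri(par)] if par is not None else [],
        )
    raw = RawTermSet(
        terms=terms, source_identifier="synthetic:scaffold", format="rdfxml"
    )
    return PinConfig(entries=pins), raw
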