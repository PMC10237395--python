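"""Read OWL ontologies (RDF/XML or Turtle) into raw class records.

The downstream hierarchy builder keeps only the *first listed* superclass of
each class, so this module must preserve the order in which ``rdfs:subClassOf``
axioms appear in the serialized document.  rdflib's RDF/XML and Turtle parsers
feed triples to the sink graph in document encounter order; a recording
``Graph`` subclass captures that order, which is stable across repeated parses
of the same byte stream.
"""

from __future__ import annotations

import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

__all__ = [
    "RawTerm",
    "RawTermSet",
    "OntologyReadError",
    "OntologyFormatError",
    "EmptyOntologyError",
    "parse_ontology",
    "extract_prefix",
]

OBOINOWL = "http://www.geneontology.org/formats/oboInOwl#"
#: OBO-in-OWL synonym annotation properties; order encodes the
#: exact > narrow > broad > related preference used when deduplicating.
SYNONYM_PROPERTIES = (
    URIRef(OBOINOWL + "hasExactSynonym"),
    URIRef(OBOINOWL + "hasNarrowSynonym"),
    URIRef(OBOINOWL + "hasBroadSynonym"),
    URIRef(OBOINOWL + "hasRelatedSynonym"),
)
#: IAO "definition" textual annotation.
DEFINITION_PROPERTY = URIRef("http://purl.obolibrary.org/obo/IAO_0000115")

OWL_THING = str(OWL.Thing)


class OntologyReadError(IOError):
    """The source path or URL could not be read."""


class OntologyFormatError(ValueError):
    """The byte stream was not parseable RDF/XML or Turtle."""


class EmptyOntologyError(ValueError):
    """The document parsed but declared no owl:Class with an IRI."""


@dataclass
class RawTerm:
    """One declared owl:Class, as serialized, before any hierarchy policy."""

    iri: str
    label: Optional[str] = None
    synonyms: list[str] = field(default_factory=list)
    definition: Optional[str] = None
    deprecated: bool = False
    #: named superclass IRIs in document encounter order (anonymous
    #: restriction superclasses dropped)
    superclass_iris: list[str] = field(default_factory=list)


@dataclass
class RawTermSet:
    """All RawTerms of one parsed document, keyed by IRI in encounter order."""

    terms: dict[str, RawTerm]
    source_identifier: str
    format: str  # "rdfxml" | "turtle"

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterable[RawTerm]:
        return iter(self.terms.values())

    def ghost_references(self) -> set[str]:
        """Superclass IRIs referenced but not declared as classes here."""
        return {
            s
            for term in self.terms.values()
            for s in term.superclass_iris
            if s not in self.terms
        }


class _RecordingGraph(Graph):
    """rdflib Graph that remembers the order in which triples were added."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.triple_log: list[tuple] = []

    def add(self, triple):  # noqa: D102 - rdflib signature
        self.triple_log.append(triple)
        return super().add(triple)


def _guess_format(source: str, data: bytes) -> str:
    lowered = source.lower()
    if lowered.endswith((".ttl", ".turtle", ".n3")):
        return "turtle"
    if lowered.endswith((".owl", ".rdf", ".xml")):
        return "rdfxml"
    head = data.lstrip()[:200]
    return "rdfxml" if head.startswith(b"<") else "turtle"


def _read_source(source: str, timeout: float) -> bytes:
    if re.match(r"^https?://", source):
        try:
            with urllib.request.urlopen(source, timeout=timeout) as resp:
                return resp.read()
        except Exception as exc:  # URLError, HTTPError, timeout
            raise OntologyReadError(f"cannot fetch ontology from {source!r}: {exc}") from exc
    path = Path(source)
    try:
        return path.read_bytes()
    except OSError as exc:
        raise OntologyReadError(f"cannot read ontology file {source!r}: {exc}") from exc


def _first_label(literals: list[Literal]) -> Optional[str]:
    """First 'en'-tagged label if any, else first seen."""
    for lit in literals:
        if lit.language == "en":
            return str(lit)
    return str(literals[0]) if literals else None


def parse_ontology(
    source: str | Path,
    format_hint: Optional[str] = None,
    timeout: float = 60.0,
) -> RawTermSet:
    """Parse an OWL file (path or HTTP(S) URL) into a :class:`RawTermSet`.

    Parameters
    ----------
    source:
        Local path or URL of an RDF/XML or Turtle document.
    format_hint:
        ``"rdfxml"`` or ``"turtle"``; guessed from the extension/content
        when omitted.
    timeout:
        Socket timeout in seconds for URL sources.

    Raises
    ------
    OntologyReadError, OntologyFormatError, EmptyOntologyError
    """
    source = str(source)
    data = _read_source(source, timeout)
    fmt = format_hint or _guess_format(source, data)
    if fmt not in ("rdfxml", "turtle"):
        raise OntologyFormatError(f"unsupported format {fmt!r} (use 'rdfxml' or 'turtle')")

    graph = _RecordingGraph()
    try:
        graph.parse(data=data, format="xml" if fmt == "rdfxml" else "turtle")
    except Exception as exc:
        raise OntologyFormatError(f"cannot parse {source!r} as {fmt}: {exc}") from exc

    # Pass 1: declared classes, in encounter order.
    terms: dict[str, RawTerm] = {}
    for s, p, o in graph.triple_log:
        if p == RDF.type and o == OWL.Class and isinstance(s, URIRef):
            iri = str(s)
            if iri not in terms:
                terms[iri] = RawTerm(iri=iri)

    if not terms:
        raise EmptyOntologyError(f"empty ontology: no owl:Class declarations in {source!r}")

    # Pass 2: annotations and superclass axioms, preserving encounter order.
    labels: dict[str, list[Literal]] = {}
    synonyms: dict[str, dict[URIRef, list[str]]] = {}
    for s, p, o in graph.triple_log:
        if not isinstance(s, URIRef):
            continue
        iri = str(s)
        if iri not in terms:
            continue
        term = terms[iri]
        if p == RDFS.subClassOf and isinstance(o, URIRef):
            sup = str(o)
            if sup != iri and sup not in term.superclass_iris:
                term.superclass_iris.append(sup)
        elif p == RDFS.label and isinstance(o, Literal):
            labels.setdefault(iri, []).append(o)
        elif p == OWL.deprecated and isinstance(o, Literal):
            if str(o).strip().lower() == "true":
                term.deprecated = True
        elif p == DEFINITION_PROPERTY and isinstance(o, Literal):
            if term.definition is None:
                term.definition = str(o)
        elif p in SYNONYM_PROPERTIES and isinstance(o, Literal):
            synonyms.setdefault(iri, {}).setdefault(p, []).append(str(o))

    for iri, lits in labels.items():
        terms[iri].label = _first_label(lits)
    for iri, by_prop in synonyms.items():
        seen: set[str] = set()
        ordered: list[str] = []
        for prop in SYNONYM_PROPERTIES:  # exact > narrow > broad > related
            for text in by_prop.get(prop, []):
                if text not in seen:
                    seen.add(text)
                    ordered.append(text)
        terms[iri].synonyms = ordered

    return RawTermSet(terms=terms, source_identifier=source, format=fmt)


_OBO_PURL_RE = re.compile(r"^https?://purl\.obolibrary\.org/obo/([A-Za-z][A-Za-z0-9]*)_[^/#]+$")


def extract_prefix(iri: str) -> str:
    """Prefix of an ontology term IRI.

    OBO PURLs of shape ``…/obo/<PREFIX>_<localid>`` yield ``PREFIX``
    uppercased; any other IRI yields the last namespace token before the
    fragment or final path segment (e.g. ``…/owl#Thing`` -> ``owl``).
    Pure and deterministic; unparseable IRIs fall back to the authority.
    """
    if not iri:
        return ""
    m = _OBO_PURL_RE.match(iri)
    if m:
        return m.group(1).upper()
    if "#" in iri:
        namespace = iri.split("#", 1)[0]
        token = namespace.rstrip("/").rsplit("/", 1)[-1]
        if token:
            return token
    # no fragment: last path segment may itself look like PREFIX_localid
    stripped = iri.rstrip("/")
    if "/" in stripped:
        last = stripped.rsplit("/", 1)[-1]
        m = re.match(r"^([A-Za-z][A-Za-z0-9]*)_[^/#]+$", last)
        if m:
            return m.group(1).upper()
        parent = stripped.rsplit("/", 1)[0].rsplit("/", 1)[-1]
        if parent and "." not in parent and ":" not in parent:
            return parent
        return last
    return stripped
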