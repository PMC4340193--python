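"""Multi-syntax RDF serialization with parse-back and isomorphism checks.

All supported syntaxes are functionally equivalent carriers of the same
triple set; they differ only in the textual format.  Equality of ontology
documents is therefore *graph isomorphism* (triple-set equality up to blank
node renaming), never byte comparison, and every serialization is required to
survive a parse → isomorphism round trip.
"""

from __future__ import annotations

import io

from rdflib import BNode, Graph
from rdflib.compare import isomorphic
from rdflib.namespace import RDF
from rdflib.plugins.serializers.rdfxml import PrettyXMLSerializer

__all__ = [
    "SYNTAXES",
    "supported_syntaxes",
    "serialize",
    "parse_document",
    "graphs_isomorphic",
    "UnsupportedSyntaxError",
    "DocumentParseError",
]

#: Canonical syntax name → rdflib format name.  OWL/XML and the N3
#: sub-dialects are deliberately not offered: no mainstream Python RDF stack
#: emits them, and the functional-equivalence contract covers what is listed.
SYNTAXES: dict[str, str] = {
    "rdfxml": "xml",
    "rdfxml-abbrev": "pretty-xml",
    "turtle": "turtle",
    "ntriples": "nt",
    "n3": "n3",
}


#: Parser format per syntax (the two RDF/XML dialects share one parser).
_PARSE_FORMATS: dict[str, str] = {**SYNTAXES, "rdfxml-abbrev": "xml"}


class UnsupportedSyntaxError(ValueError):
    def __init__(self, name: str):
        self.supported = sorted(SYNTAXES)
        super().__init__(
            f"unsupported syntax {name!r}; supported: {', '.join(self.supported)}"
        )


class DocumentParseError(ValueError):
    """The input document is not well-formed in the named syntax."""


def supported_syntaxes() -> list[str]:
    """Capability query: the syntax names ``serialize`` accepts."""
    return sorted(SYNTAXES)


def _format(syntax: str, table: dict[str, str] | None = None) -> str:
    try:
        return (table or SYNTAXES)[syntax.lower()]
    except KeyError:
        raise UnsupportedSyntaxError(syntax) from None


class _ListSafePrettyXMLSerializer(PrettyXMLSerializer):
    """Abbreviated RDF/XML that keeps RDF lists faithful.

    rdflib's pretty-xml writer abbreviates every RDF list to
    ``rdf:parseType="Collection"``, a form that can only hold resources, so
    literal list items (e.g. the string members of an ``owl:DataRange``
    ``owl:oneOf``) silently re-parse as IRIs.  Writing list cells as explicit
    ``rdf:first``/``rdf:rest`` descriptions preserves the triple set.
    """

    def predicate(self, predicate, object, depth: int = 1) -> None:
        serialized = getattr(self, "_PrettyXMLSerializer__serialized")
        if (
            isinstance(object, BNode)
            and (object, RDF.first, None) in self.store
            and object not in serialized
        ):
            self.writer.push(predicate)
            self.subject(object, depth + 1)
            self.writer.pop(predicate)
            return
        super().predicate(predicate, object, depth)


def serialize(graph: Graph, syntax: str = "rdfxml") -> str:
    """Serialize the graph in the named syntax (case-insensitive), UTF-8 text.

    Deterministic for a fixed graph: the same graph yields the same bytes.
    """
    fmt = _format(syntax)
    if fmt == "pretty-xml":
        buf = io.BytesIO()
        _ListSafePrettyXMLSerializer(graph).serialize(buf, encoding="utf-8")
        return buf.getvalue().decode("utf-8")
    return graph.serialize(format=fmt)


def parse_document(text: str, syntax: str = "rdfxml") -> Graph:
    """Parse a document back into a graph containing exactly its triples."""
    fmt = _format(syntax, _PARSE_FORMATS)
    g = Graph()
    try:
        g.parse(data=text, format=fmt)
    except Exception as exc:
        raise DocumentParseError(f"cannot parse as {syntax}: {exc}") from exc
    return g


def graphs_isomorphic(g1: Graph, g2: Graph) -> bool:
    """True iff the graphs are equal up to blank-node renaming."""
    return isomorphic(g1, g2)
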