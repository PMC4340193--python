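"""IR → OWL transformation.

The mapping follows two rules.  **Structural rule:** every source class
becomes an ``owl:Class`` (annotated with its fully qualified source name via a
framework annotation property), inheritance becomes ``rdfs:subClassOf``,
atomic fields become ``owl:DatatypeProperty`` nodes ranging over XSD
datatypes, reference and collection fields become ``owl:ObjectProperty``
nodes, enumerations become classes equivalent to an ``owl:oneOf`` list of
individuals, and instance records become named individuals with literal and
object-property assertions.  **Semantic rule:** each marker adds exactly one
OWL construct — equivalence, sameness/difference, property character
(symmetric/transitive/inverse), or an anonymous ``owl:Restriction``
superclass carrying a value or cardinality constraint on one property.

OWL properties are global, unlike fields, which belong to a class.  When two
classes declare the same field name with the same range the mapper emits one
property whose domain is the union of the declaring classes; conflicting
ranges are a hard error rather than a silent merge.

All blank nodes carry deterministic labels derived from the model element
they describe, so re-running any stage is idempotent (the graph is a set) and
serialization is reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .model import (
    AtomicKind,
    CARDINALITY_MARKERS,
    ClassModel,
    FieldKind,
    FieldModel,
    InstanceRecord,
    Marker,
    OBJECT_PROPERTY_ONLY_MARKERS,
    SemanticAnnotation,
)

__all__ = [
    "MappingConfig",
    "MappingError",
    "map_structure",
    "map_instances",
    "apply_semantics",
    "build_restriction",
    "mint_iri",
    "atomic_to_datatype",
    "map_model",
]

#: Default namespace of the framework's own annotation property that records
#: the fully qualified source-class name on each emitted owl:Class.
DEFAULT_SOURCE_NAMESPACE = "http://owlbind.dev/semantic#"


class MappingError(ValueError):
    """The model cannot be expressed under the mapping rules."""


@dataclass(frozen=True)
class MappingConfig:
    """Knobs of the IR→OWL mapping.

    base_iri
        Absolute IRI, ending in a fragment separator, under which classes,
        properties and individuals are minted.
    source_annotation_local_name
        Local name of the annotation property carrying the qualified source
        class name (``javaclass`` by convention).
    cardinality_datatype
        Datatype of cardinality restriction literals; ``xsd:int`` by
        convention, while field ranges use ``xsd:integer`` — both appear in
        emitted documents and both are configurable.
    individual_naming
        ``"sequential"`` mints ``Class_0, Class_1, ...`` in record order;
        ``"identifier-field"`` uses the value of the class's identifier field.
    """

    base_iri: str = "http://owlbind.dev/model#"
    source_annotation_namespace: str = DEFAULT_SOURCE_NAMESPACE
    source_annotation_local_name: str = "javaclass"
    cardinality_datatype: URIRef = XSD.int
    individual_naming: str = "sequential"

    def __post_init__(self) -> None:
        if ":" not in self.base_iri:
            raise MappingError(f"base_iri {self.base_iri!r} is not an absolute IRI")
        if not self.base_iri.endswith(("#", "/")):
            object.__setattr__(self, "base_iri", self.base_iri + "#")
        if self.individual_naming not in ("sequential", "identifier-field"):
            raise MappingError(
                f"individual_naming must be 'sequential' or 'identifier-field', "
                f"got {self.individual_naming!r}"
            )

    @property
    def source_annotation_property(self) -> URIRef:
        return URIRef(self.source_annotation_namespace + self.source_annotation_local_name)


_XSD_BY_ATOMIC = {
    AtomicKind.STRING: XSD.string,
    AtomicKind.INTEGER: XSD.integer,
    AtomicKind.DECIMAL: XSD.double,
    AtomicKind.BOOLEAN: XSD.boolean,
    AtomicKind.DATE: XSD.date,
    AtomicKind.DATETIME: XSD.dateTime,
}


def atomic_to_datatype(kind: AtomicKind) -> URIRef:
    """XSD datatype for an atomic field kind (total function)."""
    return _XSD_BY_ATOMIC[kind]


def mint_iri(kind: str, *names, cfg: MappingConfig) -> URIRef:
    """Deterministically mint the IRI for a class, property, or individual.

    ``mint_iri("class", "Person")`` → ``base#Person``;
    ``mint_iri("property", "firstname")`` → ``base#firstname``;
    ``mint_iri("individual", "Person", 0)`` → ``base#Person_0``.
    """
    if kind == "class":
        (name,) = names
        return URIRef(cfg.base_iri + str(name))
    if kind == "property":
        (name,) = names
        return URIRef(cfg.base_iri + str(name))
    if kind == "individual":
        cls_name, key = names
        return URIRef(f"{cfg.base_iri}{cls_name}_{key}")
    raise MappingError(f"unknown IRI kind {kind!r}")


def _new_graph(cfg: MappingConfig) -> Graph:
    g = Graph()
    g.bind("owl", OWL)
    g.bind("rdf", RDF)
    g.bind("rdfs", RDFS)
    g.bind("xsd", XSD)
    g.bind("semantic", Namespace(cfg.source_annotation_namespace))
    g.bind("", Namespace(cfg.base_iri))
    ontology_iri = URIRef(cfg.base_iri.rstrip("#/"))
    g.add((ontology_iri, RDF.type, OWL.Ontology))
    return g


@dataclass
class _PropertyPlan:
    """One global OWL property merged from equally named fields."""

    name: str
    is_object: bool
    range_node: URIRef
    domains: list[str] = _dcfield(default_factory=list)  # declaring class names


def _plan_properties(classes: list[ClassModel]) -> dict[str, _PropertyPlan]:
    plans: dict[str, _PropertyPlan] = {}
    for cls in classes:
        for f in cls.fields:
            if f.kind is FieldKind.ATOMIC:
                is_object = False
                rng: URIRef | str = atomic_to_datatype(f.atomic_kind)
            else:
                is_object = True
                rng = f.target_class
            plan = plans.get(f.name)
            if plan is None:
                plans[f.name] = _PropertyPlan(f.name, is_object, rng, [cls.simple_name])
            else:
                if plan.is_object != is_object or plan.range_node != rng:
                    raise MappingError(
                        f"field {f.name!r} is declared with incompatible ranges "
                        f"(OWL properties are global); offending class: {cls.simple_name}"
                    )
                plan.domains.append(cls.simple_name)
    return plans


def map_structure(classes: list[ClassModel], cfg: MappingConfig | None = None) -> Graph:
    """Emit the structural ontology for a validated model.

    One ``owl:Class`` per source class carrying its qualified name, one
    global property per distinct field name, ``rdfs:subClassOf`` links for
    inheritance, and an ``owl:oneOf`` equivalent class per enumeration.
    """
    cfg = cfg or MappingConfig()
    g = _new_graph(cfg)
    minted: dict[URIRef, tuple] = {}

    def mint(kind: str, *names) -> URIRef:
        iri = mint_iri(kind, *names, cfg=cfg)
        prev = minted.setdefault(iri, (kind, names))
        if prev != (kind, names):
            raise MappingError(
                f"IRI collision: {prev} and {(kind, names)} both mint <{iri}>"
            )
        return iri

    g.add((cfg.source_annotation_property, RDF.type, OWL.AnnotationProperty))

    for cls in classes:
        c_iri = mint("class", cls.simple_name)
        g.add((c_iri, RDF.type, OWL.Class))
        g.add((c_iri, cfg.source_annotation_property, Literal(cls.qualified_name)))
        if cls.superclass:
            g.add((c_iri, RDFS.subClassOf, mint("class", cls.superclass)))
        if cls.is_enumeration:
            enum_cls = BNode(f"oneof_{cls.simple_name}")
            g.add((c_iri, OWL.equivalentClass, enum_cls))
            g.add((enum_cls, RDF.type, OWL.Class))
            members = [
                mint("individual", cls.simple_name, lit) for lit in cls.enum_literals
            ]
            for m, lit in zip(members, cls.enum_literals):
                g.add((m, RDF.type, c_iri))
            head = _rdf_list(g, f"oneof_{cls.simple_name}", members)
            g.add((enum_cls, OWL.oneOf, head))

    for plan in _plan_properties(classes).values():
        p_iri = mint("property", plan.name)
        if plan.is_object:
            g.add((p_iri, RDF.type, OWL.ObjectProperty))
            rng = mint("class", plan.range_node)
        else:
            g.add((p_iri, RDF.type, OWL.DatatypeProperty))
            rng = plan.range_node
        g.add((p_iri, RDFS.range, rng))
        if len(plan.domains) == 1:
            g.add((p_iri, RDFS.domain, mint("class", plan.domains[0])))
        else:
            union = BNode(f"uniondomain_{plan.name}")
            g.add((p_iri, RDFS.domain, union))
            g.add((union, RDF.type, OWL.Class))
            head = _rdf_list(
                g,
                f"uniondomain_{plan.name}",
                [mint("class", d) for d in plan.domains],
            )
            g.add((union, OWL.unionOf, head))
    return g


def _rdf_list(g: Graph, label: str, items: list) -> URIRef | BNode:
    """Build a well-formed RDF list with deterministic cell labels."""
    if not items:
        return RDF.nil
    head = BNode(f"{label}_cell0")
    cur = head
    for i, item in enumerate(items):
        g.add((cur, RDF.first, item))
        if i + 1 < len(items):
            nxt = BNode(f"{label}_cell{i + 1}")
            g.add((cur, RDF.rest, nxt))
            cur = nxt
        else:
            g.add((cur, RDF.rest, RDF.nil))
    return head


def _literal_for(value, datatype: URIRef | None) -> Literal:
    if isinstance(value, bool):
        return Literal(value)
    if datatype is None:
        return Literal(value)
    return Literal(str(value) if datatype in (XSD.date, XSD.dateTime) else value,
                   datatype=datatype)


def map_instances(
    graph: Graph,
    instances: list[InstanceRecord],
    cfg: MappingConfig | None = None,
    classes: list[ClassModel] | None = None,
) -> Graph:
    """Add one named individual per record to an already structured graph.

    Sequential naming (``Person_0, Person_1, ...``) needs only the graph;
    identifier-field naming additionally needs ``classes`` to know which
    field is the identifier.  Atomic values become typed literals matching
    the property's declared range; reference values become object-property
    assertions between individuals (cycles are fine — each record is emitted
    exactly once because all individual IRIs are minted before any triple).
    """
    cfg = cfg or MappingConfig()
    if cfg.individual_naming == "identifier-field" and classes is None:
        raise MappingError("identifier-field naming requires the class models")
    by_class: dict[str, ClassModel] = {c.simple_name: c for c in (classes or [])}

    def id_field(name: str) -> str | None:
        cur = by_class.get(name)
        while cur is not None:
            for f in cur.fields:
                if f.is_identifier:
                    return f.name
            cur = by_class.get(cur.superclass) if cur.superclass else None
        return None

    # mint every individual IRI first so cycles resolve
    counters: dict[str, int] = {}
    iri_of: dict[tuple[str, object], URIRef] = {}
    for rec in instances:
        c_iri = mint_iri("class", rec.class_name, cfg=cfg)
        if (c_iri, RDF.type, OWL.Class) not in graph:
            raise MappingError(
                f"instance {rec.class_name}/{rec.local_id}: class {rec.class_name} "
                f"is not in the graph (map the structure first)"
            )
        key: object
        fid = id_field(rec.class_name) if cfg.individual_naming == "identifier-field" else None
        if fid is not None and fid in rec.values:
            key = rec.values[fid]
        else:
            k = counters.get(rec.class_name, 0)
            counters[rec.class_name] = k + 1
            key = k
        iri_of[(rec.class_name, rec.local_id)] = mint_iri(
            "individual", rec.class_name, key, cfg=cfg
        )

    for rec in instances:
        ind = iri_of[(rec.class_name, rec.local_id)]
        g_cls = mint_iri("class", rec.class_name, cfg=cfg)
        graph.add((ind, RDF.type, g_cls))
        for fname, value in rec.values.items():
            prop = mint_iri("property", fname, cfg=cfg)
            is_object = (prop, RDF.type, OWL.ObjectProperty) in graph
            if not is_object and (prop, RDF.type, OWL.DatatypeProperty) not in graph:
                raise MappingError(
                    f"instance {rec.class_name}/{rec.local_id}: field {fname!r} "
                    f"has no mapped property"
                )
            rng = graph.value(prop, RDFS.range)
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if is_object:
                    target = _resolve_object_value(graph, rng, item, iri_of, cfg)
                    graph.add((ind, prop, target))
                else:
                    graph.add((ind, prop, _literal_for(item, rng)))
    return graph


def _resolve_object_value(graph, range_node, item, iri_of, cfg) -> URIRef:
    # enumeration targets take the literal name; others take a record local_id
    def local_name(node) -> str:
        return str(node).rsplit("#", 1)[-1].rsplit("/", 1)[-1]

    if range_node is not None and (range_node, OWL.equivalentClass, None) in graph:
        for enum_cls in graph.objects(range_node, OWL.equivalentClass):
            if (enum_cls, OWL.oneOf, None) in graph:
                return mint_iri("individual", local_name(range_node), item, cfg=cfg)
    # accept the range class and its (transitive) subclasses
    acceptable: set[str] = set()
    if range_node is not None:
        frontier = [range_node]
        while frontier:
            node = frontier.pop()
            name = local_name(node)
            if name in acceptable:
                continue
            acceptable.add(name)
            frontier.extend(
                s for s in graph.subjects(RDFS.subClassOf, node)
                if isinstance(s, URIRef)
            )
    for (cls_name, local_id), iri in iri_of.items():
        if local_id == item and (not acceptable or cls_name in acceptable):
            return iri
    raise MappingError(f"reference value {item!r} does not resolve to any record")


_CARDINALITY_PREDICATE = {
    Marker.CARDINALITY: OWL.cardinality,
    Marker.MAX_CARDINALITY: OWL.maxCardinality,
    Marker.MIN_CARDINALITY: OWL.minCardinality,
}

_RESTRICTION_MARKERS = frozenset(
    {Marker.ALL_VALUES_FROM, Marker.SOME_VALUES_FROM} | CARDINALITY_MARKERS
)


def build_restriction(
    graph: Graph,
    cls: ClassModel,
    field: FieldModel,
    annotation: SemanticAnnotation,
    cfg: MappingConfig | None = None,
) -> BNode:
    """Attach an anonymous ``owl:Restriction`` superclass to ``cls``.

    Cardinality markers emit an integer literal typed per
    ``cfg.cardinality_datatype``; value markers emit ``owl:allValuesFrom`` /
    ``owl:someValuesFrom``.  The string-values form of SomeValuesFrom builds
    an ``owl:DataRange`` whose ``owl:oneOf`` is an RDF list of string
    literals.
    """
    cfg = cfg or MappingConfig()
    marker = annotation.marker
    if marker not in _RESTRICTION_MARKERS:
        raise MappingError(f"{marker.value} does not build a restriction")
    if marker in CARDINALITY_MARKERS and (annotation.number is None or annotation.number < 0):
        raise MappingError(
            f"{cls.simple_name}.{field.name}: {marker.value} needs a non-negative integer"
        )
    c_iri = mint_iri("class", cls.simple_name, cfg=cfg)
    p_iri = mint_iri("property", field.name, cfg=cfg)
    node = BNode(f"restriction_{cls.simple_name}_{field.name}_{marker.value}")
    graph.add((node, RDF.type, OWL.Restriction))
    graph.add((node, OWL.onProperty, p_iri))
    if marker in CARDINALITY_MARKERS:
        graph.add(
            (node, _CARDINALITY_PREDICATE[marker],
             Literal(str(annotation.number), datatype=cfg.cardinality_datatype))
        )
    elif marker is Marker.ALL_VALUES_FROM:
        graph.add((node, OWL.allValuesFrom, URIRef(annotation.resource)))
    elif annotation.resource is not None:  # SomeValuesFrom, resource form
        graph.add((node, OWL.someValuesFrom, URIRef(annotation.resource)))
    else:  # SomeValuesFrom, stringValues form
        dr = BNode(f"datarange_{cls.simple_name}_{field.name}")
        graph.add((node, OWL.someValuesFrom, dr))
        graph.add((dr, RDF.type, OWL.DataRange))
        head = _rdf_list(
            graph,
            f"datarange_{cls.simple_name}_{field.name}",
            [Literal(s, datatype=XSD.string) for s in annotation.string_values or ()],
        )
        graph.add((dr, OWL.oneOf, head))
    graph.add((c_iri, RDFS.subClassOf, node))
    return node


def apply_semantics(
    graph: Graph, classes: list[ClassModel], cfg: MappingConfig | None = None
) -> Graph:
    """Translate every semantic marker into its OWL construct.

    Class-level: EquivalentClass → ``owl:equivalentClass``, SameAs →
    ``owl:sameAs``, DifferentFrom → ``owl:differentFrom``, AllDifferent →
    ``rdf:type`` of the referenced resource.  Field-level: EquivalentProperty
    → ``owl:equivalentProperty``; Symmetric/Transitive → ``rdf:type
    owl:SymmetricProperty``/``owl:TransitiveProperty``; Inverse →
    ``owl:inverseOf`` (the three property-character markers are legal only on
    object properties); the value/cardinality markers add restriction
    superclasses via :func:`build_restriction`.  Idempotent: re-application
    adds no triples.
    """
    cfg = cfg or MappingConfig()
    for cls in classes:
        c_iri = mint_iri("class", cls.simple_name, cfg=cfg)
        for ann in cls.annotations:
            if ann.marker is Marker.EQUIVALENT_CLASS:
                graph.add((c_iri, OWL.equivalentClass, URIRef(ann.resource)))
            elif ann.marker is Marker.SAME_AS:
                graph.add((c_iri, OWL.sameAs, URIRef(ann.resource)))
            elif ann.marker is Marker.DIFFERENT_FROM:
                graph.add((c_iri, OWL.differentFrom, URIRef(ann.resource)))
            elif ann.marker is Marker.ALL_DIFFERENT:
                graph.add((c_iri, RDF.type, URIRef(ann.resource)))
            else:
                raise MappingError(
                    f"{cls.simple_name}: marker {ann.marker.value} is not class-level"
                )
        for f in cls.fields:
            p_iri = mint_iri("property", f.name, cfg=cfg)
            for ann in f.annotations:
                if ann.marker in OBJECT_PROPERTY_ONLY_MARKERS and f.kind is FieldKind.ATOMIC:
                    raise MappingError(
                        f"{cls.simple_name}.{f.name}: {ann.marker.value} applies only "
                        f"to object properties"
                    )
                if ann.marker is Marker.EQUIVALENT_PROPERTY:
                    graph.add((p_iri, OWL.equivalentProperty, URIRef(ann.resource)))
                elif ann.marker is Marker.SYMMETRIC:
                    graph.add((p_iri, RDF.type, OWL.SymmetricProperty))
                elif ann.marker is Marker.TRANSITIVE:
                    graph.add((p_iri, RDF.type, OWL.TransitiveProperty))
                elif ann.marker is Marker.INVERSE:
                    graph.add((p_iri, OWL.inverseOf, URIRef(ann.resource)))
                elif ann.marker in _RESTRICTION_MARKERS:
                    build_restriction(graph, cls, f, ann, cfg)
                else:
                    raise MappingError(
                        f"{cls.simple_name}.{f.name}: marker {ann.marker.value} "
                        f"is not field-level"
                    )
    return graph


def map_model(
    classes: list[ClassModel],
    instances: list[InstanceRecord] = (),
    cfg: MappingConfig | None = None,
) -> Graph:
    """Full pipeline: structure, then semantics, then instances."""
    cfg = cfg or MappingConfig()
    g = map_structure(classes, cfg)
    apply_semantics(g, classes, cfg)
    map_instances(g, list(instances), cfg, classes=classes)
    return g
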