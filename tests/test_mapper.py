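"""Structural and semantic mapping against hand-enumerated expected triples."""

import pytest
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from owlbind import (
    AllDifferent,
    AllValuesFrom,
    AtomicKind,
    Cardinality,
    ClassModel,
    DifferentFrom,
    EquivalentClass,
    EquivalentProperty,
    FieldKind,
    FieldModel,
    InstanceRecord,
    Inverse,
    MappingConfig,
    MappingError,
    MaxCardinality,
    MinCardinality,
    SameAs,
    SemanticAnnotation,
    SomeValuesFrom,
    Symmetric,
    Transitive,
    apply_semantics,
    atomic_to_datatype,
    build_restriction,
    map_instances,
    map_model,
    map_structure,
    mint_iri,
)
from owlbind.model import Marker

from conftest import BASE

CFG = MappingConfig(base_iri=BASE)
SEM = CFG.source_annotation_property


def n(local: str) -> URIRef:
    return URIRef(BASE + local)


def _payload(graph: Graph) -> set:
    """All triples except the fixed ontology header."""
    header = {
        (URIRef(BASE.rstrip("#")), RDF.type, OWL.Ontology),
        (SEM, RDF.type, OWL.AnnotationProperty),
    }
    return set(graph) - header


def _cls(name, **kw):
    return ClassModel(simple_name=name, qualified_name=f"cz.zcu.kiv.{name}", **kw)


def test_structural_mapping_of_worked_example(person_model):
    g = map_structure(person_model, CFG)
    expected = {
        (n("Person"), RDF.type, OWL.Class),
        (n("Person"), SEM, Literal("cz.zcu.kiv.Person")),
        (n("ResearchGroup"), RDF.type, OWL.Class),
        (n("ResearchGroup"), SEM, Literal("cz.zcu.kiv.ResearchGroup")),
        (n("researchGroups"), RDF.type, OWL.ObjectProperty),
        (n("researchGroups"), RDFS.domain, n("Person")),
        (n("researchGroups"), RDFS.range, n("ResearchGroup")),
        (n("firstname"), RDF.type, OWL.DatatypeProperty),
        (n("firstname"), RDFS.domain, n("Person")),
        (n("firstname"), RDFS.range, XSD.string),
        (n("id"), RDF.type, OWL.DatatypeProperty),
        (n("id"), RDFS.domain, n("Person")),
        (n("id"), RDFS.range, XSD.integer),
    }
    assert _payload(g) == expected


def test_empty_model_yields_header_only():
    g = map_structure([], CFG)
    assert _payload(g) == set()
    assert len(g) == 2  # ontology node + source annotation property


def test_three_class_chain_subclassof_path():
    model = [_cls("A"), _cls("B", superclass="A"), _cls("C", superclass="B")]
    g = map_structure(model, CFG)
    sub = set(g.triples((None, RDFS.subClassOf, None)))
    # enumerated by hand: exactly the two direct links, no transitive closure
    assert sub == {
        (n("B"), RDFS.subClassOf, n("A")),
        (n("C"), RDFS.subClassOf, n("B")),
    }


def test_enumeration_maps_to_oneof_individuals():
    model = [_cls("Gender", is_enumeration=True, enum_literals=("MALE", "FEMALE"))]
    g = map_structure(model, CFG)
    assert (n("Gender"), RDF.type, OWL.Class) in g
    anon = g.value(n("Gender"), OWL.equivalentClass)
    assert isinstance(anon, BNode)
    members = list(g.items(g.value(anon, OWL.oneOf)))
    assert members == [n("Gender_MALE"), n("Gender_FEMALE")]
    for m in members:
        assert (m, RDF.type, n("Gender")) in g


def test_shared_field_name_same_range_gets_union_domain():
    f = FieldModel("title", FieldKind.ATOMIC, atomic_kind=AtomicKind.STRING)
    g = map_structure([_cls("A", fields=(f,)), _cls("B", fields=(f,))], CFG)
    assert len(list(g.triples((None, RDF.type, OWL.DatatypeProperty)))) == 1
    union = g.value(n("title"), RDFS.domain)
    assert isinstance(union, BNode)
    assert set(g.items(g.value(union, OWL.unionOf))) == {n("A"), n("B")}


def test_shared_field_name_conflicting_ranges_is_an_error():
    fa = FieldModel("x", FieldKind.ATOMIC, atomic_kind=AtomicKind.STRING)
    fb = FieldModel("x", FieldKind.ATOMIC, atomic_kind=AtomicKind.INTEGER)
    with pytest.raises(MappingError, match="incompatible ranges"):
        map_structure([_cls("A", fields=(fa,)), _cls("B", fields=(fb,))], CFG)
    fc = FieldModel("x", FieldKind.REFERENCE, target_class="A")
    with pytest.raises(MappingError, match="incompatible ranges"):
        map_structure([_cls("A", fields=(fa,)), _cls("B", fields=(fc,))], CFG)


def test_inherited_fields_are_mapped_once_on_the_declaring_class():
    f = FieldModel("x", FieldKind.ATOMIC, atomic_kind=AtomicKind.STRING)
    model = [_cls("A", fields=(f,)), _cls("B", superclass="A")]
    g = map_structure(model, CFG)
    assert g.value(n("x"), RDFS.domain) == n("A")


# ---------------------------------------------------------------------------
# instances
# ---------------------------------------------------------------------------


def test_single_instance_with_literal(person_model):
    g = map_structure(person_model, CFG)
    before = set(g)
    map_instances(g, [InstanceRecord("Person", 1, {"firstname": "Jan"})], CFG)
    assert set(g) - before == {
        (n("Person_0"), RDF.type, n("Person")),
        (n("Person_0"), n("firstname"), Literal("Jan", datatype=XSD.string)),
    }


def test_sequential_naming_starts_at_zero(person_model):
    g = map_structure(person_model, CFG)
    map_instances(
        g,
        [InstanceRecord("Person", "a", {}), InstanceRecord("Person", "b", {})],
        CFG,
    )
    assert (n("Person_0"), RDF.type, n("Person")) in g
    assert (n("Person_1"), RDF.type, n("Person")) in g


def test_identifier_field_naming(person_model):
    cfg = MappingConfig(base_iri=BASE, individual_naming="identifier-field")
    g = map_structure(person_model, cfg)
    map_instances(
        g, [InstanceRecord("Person", "a", {"id": 37})], cfg, classes=person_model
    )
    assert (n("Person_37"), RDF.type, n("Person")) in g
    with pytest.raises(MappingError, match="identifier-field"):
        map_instances(Graph(), [], cfg)


def test_reference_cycle_emits_each_record_once():
    f = FieldModel("peer", FieldKind.REFERENCE, target_class="Node")
    model = [_cls("Node", fields=(f,))]
    g = map_structure(model, CFG)
    before = set(g)
    recs = [
        InstanceRecord("Node", "x", {"peer": "y"}),
        InstanceRecord("Node", "y", {"peer": "x"}),
    ]
    map_instances(g, recs, CFG)
    # hand enumeration for the 2-cycle: 2 type triples + 2 assertions
    assert set(g) - before == {
        (n("Node_0"), RDF.type, n("Node")),
        (n("Node_1"), RDF.type, n("Node")),
        (n("Node_0"), n("peer"), n("Node_1")),
        (n("Node_1"), n("peer"), n("Node_0")),
    }


def test_instance_of_unmapped_class_is_an_error(person_model):
    g = map_structure(person_model, CFG)
    with pytest.raises(MappingError, match="Ghost"):
        map_instances(g, [InstanceRecord("Ghost", 1, {})], CFG)


def test_atomic_literals_take_the_declared_datatype(eeg_model):
    g = map_model(eeg_model, [InstanceRecord(
        "Experiment",
        "e", {"id": 3, "startTime": "2013-05-02T10:00:00", "temperature": 21.5},
    )], CFG)
    ind = n("Experiment_0")
    assert g.value(ind, n("id")) == Literal(3, datatype=XSD.integer)
    assert g.value(ind, n("startTime")) == Literal(
        "2013-05-02T10:00:00", datatype=XSD.dateTime
    )
    assert g.value(ind, n("temperature")) == Literal(21.5, datatype=XSD.double)


# ---------------------------------------------------------------------------
# semantics: the full marker/construct table
# ---------------------------------------------------------------------------

EXT = "http://www.kiv.zcu.cz/Probe"


def _probe_graph(class_anns=(), field_anns=(), field_kind=FieldKind.REFERENCE):
    field = (
        FieldModel("probe", field_kind, target_class="Other", annotations=tuple(field_anns))
        if field_kind is not FieldKind.ATOMIC
        else FieldModel("probe", field_kind, atomic_kind=AtomicKind.STRING,
                        annotations=tuple(field_anns))
    )
    model = [_cls("Thing", fields=(field,), annotations=tuple(class_anns)), _cls("Other")]
    g = map_structure(model, CFG)
    apply_semantics(g, model, CFG)
    return g


def _restriction_of(g, prop):
    nodes = [
        r for r in g.objects(n("Thing"), RDFS.subClassOf)
        if (r, RDF.type, OWL.Restriction) in g and g.value(r, OWL.onProperty) == prop
    ]
    assert len(nodes) == 1
    return nodes[0]


CARD_1 = Literal("1", datatype=XSD.int)

# one entry per supported marker: expected construct, built by hand
MATRIX = [
    ("EquivalentClass", "class", lambda g: (n("Thing"), OWL.equivalentClass, URIRef(EXT)) in g),
    ("SameAs", "class", lambda g: (n("Thing"), OWL.sameAs, URIRef(EXT)) in g),
    ("DifferentFrom", "class", lambda g: (n("Thing"), OWL.differentFrom, URIRef(EXT)) in g),
    ("AllDifferent", "class", lambda g: (n("Thing"), RDF.type, URIRef(EXT)) in g),
    ("EquivalentProperty", "field",
     lambda g: (n("probe"), OWL.equivalentProperty, URIRef(EXT)) in g),
    ("Symmetric", "field", lambda g: (n("probe"), RDF.type, OWL.SymmetricProperty) in g),
    ("Transitive", "field", lambda g: (n("probe"), RDF.type, OWL.TransitiveProperty) in g),
    ("Inverse", "field", lambda g: (n("probe"), OWL.inverseOf, URIRef(EXT)) in g),
    ("AllValuesFrom", "field",
     lambda g: g.value(_restriction_of(g, n("probe")), OWL.allValuesFrom) == URIRef(EXT)),
    ("SomeValuesFrom", "field",
     lambda g: g.value(_restriction_of(g, n("probe")), OWL.someValuesFrom) == URIRef(EXT)),
    ("Cardinality", "field",
     lambda g: g.value(_restriction_of(g, n("probe")), OWL.cardinality) == CARD_1),
    ("MaxCardinality", "field",
     lambda g: g.value(_restriction_of(g, n("probe")), OWL.maxCardinality) == CARD_1),
    ("MinCardinality", "field",
     lambda g: g.value(_restriction_of(g, n("probe")), OWL.minCardinality) == CARD_1),
]


def _make_annotation(marker_name):
    marker = Marker(marker_name)
    if marker in (Marker.CARDINALITY, Marker.MAX_CARDINALITY, Marker.MIN_CARDINALITY):
        return SemanticAnnotation(marker, number=1)
    if marker in (Marker.SYMMETRIC, Marker.TRANSITIVE):
        return SemanticAnnotation(marker)
    return SemanticAnnotation(marker, resource=EXT)


@pytest.mark.parametrize("marker_name, level, check", MATRIX, ids=[m[0] for m in MATRIX])
def test_each_marker_emits_its_owl_construct(marker_name, level, check):
    ann = _make_annotation(marker_name)
    if level == "class":
        g = _probe_graph(class_anns=[ann])
    else:
        g = _probe_graph(field_anns=[ann])
    assert check(g)


def test_markers_cover_the_whole_vocabulary():
    assert {m[0] for m in MATRIX} == {m.value for m in Marker}


def test_apply_semantics_without_annotations_is_identity(person_model):
    g = map_structure(person_model, CFG)
    before = set(g)
    apply_semantics(g, person_model, CFG)
    assert set(g) == before


def test_apply_semantics_is_idempotent(annotated_person_model):
    g = map_structure(annotated_person_model, CFG)
    apply_semantics(g, annotated_person_model, CFG)
    once = set(g)
    apply_semantics(g, annotated_person_model, CFG)
    assert set(g) == once


def test_property_character_markers_reject_atomic_fields():
    for ann in (Symmetric(), Transitive(), Inverse(EXT)):
        with pytest.raises(MappingError, match="object properties"):
            _probe_graph(field_anns=[ann], field_kind=FieldKind.ATOMIC)


def test_annotated_person_worked_example(annotated_person_model, cfg):
    g = map_structure(annotated_person_model, cfg)
    apply_semantics(g, annotated_person_model, cfg)
    person = n("Person")
    assert (person, OWL.equivalentClass, URIRef("http://cz.zcu.kiv/TestedSubject")) in g
    restrictions = [
        r for r in g.objects(person, RDFS.subClassOf)
        if (r, RDF.type, OWL.Restriction) in g
    ]
    assert len(restrictions) == 3
    by_prop = {g.value(r, OWL.onProperty): r for r in restrictions}
    assert g.value(by_prop[n("dateofBirth")], OWL.cardinality) == CARD_1
    assert g.value(by_prop[n("researchGroups")], OWL.minCardinality) == CARD_1
    datarange = g.value(by_prop[n("firstname")], OWL.someValuesFrom)
    assert (datarange, RDF.type, OWL.DataRange) in g
    head = g.value(datarange, OWL.oneOf)
    assert g.value(head, RDF.first) == Literal(
        "http://cz.zcu.kiv/GivenNames", datatype=XSD.string
    )
    assert g.value(head, RDF.rest) == RDF.nil


def test_restriction_edge_cases(person_model):
    g = map_structure(person_model, CFG)
    person = next(c for c in person_model if c.simple_name == "Person")
    fld = person.field("firstname")
    node = build_restriction(g, person, fld, MinCardinality(0), CFG)
    assert g.value(node, OWL.minCardinality) == Literal("0", datatype=XSD.int)
    with pytest.raises(MappingError, match="non-negative"):
        build_restriction(
            g, person, fld, SemanticAnnotation(Marker.CARDINALITY, number=-1), CFG
        )
    with pytest.raises(MappingError, match="restriction"):
        build_restriction(g, person, fld, Symmetric(), CFG)


# ---------------------------------------------------------------------------
# minting, datatypes, invariants
# ---------------------------------------------------------------------------


def test_mint_iri_conventions():
    assert mint_iri("class", "Person", cfg=CFG) == URIRef(BASE + "Person")
    assert mint_iri("property", "firstname", cfg=CFG) == URIRef(BASE + "firstname")
    assert mint_iri("individual", "Person", 0, cfg=CFG) == URIRef(BASE + "Person_0")
    assert mint_iri("class", "Person", cfg=CFG) == mint_iri("class", "Person", cfg=CFG)
    with pytest.raises(MappingError, match="kind"):
        mint_iri("galaxy", "X", cfg=CFG)


def test_minting_collisions_are_detected():
    # a field named exactly like a class would mint the class IRI again
    f = FieldModel("Person", FieldKind.ATOMIC, atomic_kind=AtomicKind.STRING)
    with pytest.raises(MappingError, match="collision"):
        map_structure([_cls("Person", fields=(f,))], CFG)


@pytest.mark.parametrize(
    "kind, xsd",
    [
        (AtomicKind.STRING, XSD.string),
        (AtomicKind.INTEGER, XSD.integer),
        (AtomicKind.DECIMAL, XSD.double),
        (AtomicKind.BOOLEAN, XSD.boolean),
        (AtomicKind.DATE, XSD.date),
        (AtomicKind.DATETIME, XSD.dateTime),
    ],
)
def test_atomic_datatype_table(kind, xsd):
    assert atomic_to_datatype(kind) == xsd


def test_class_and_property_bijection(eeg_model):
    g = map_model(eeg_model, [], CFG)
    named_classes = {
        s for s in g.subjects(RDF.type, OWL.Class)
        if isinstance(s, URIRef) and str(s).startswith(BASE)
    }
    assert len(named_classes) == len(eeg_model)
    props = set(g.subjects(RDF.type, OWL.DatatypeProperty)) | set(
        g.subjects(RDF.type, OWL.ObjectProperty)
    )
    field_names = {f.name for c in eeg_model for f in c.fields}
    assert {str(p)[len(BASE):] for p in props} == field_names


def test_base_iri_must_be_absolute():
    with pytest.raises(MappingError, match="absolute"):
        MappingConfig(base_iri="not-an-iri")
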