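"""Portable intermediate representation of an annotated object model.

The IR decouples how a model is declared (native Python classes, a YAML/JSON
model document) from how it is mapped to OWL.  A model is a list of
:class:`ClassModel` objects: plain data-holding classes with typed fields,
single inheritance, enumerations, and optional semantic markers
(:class:`SemanticAnnotation`) that request richer OWL constructs than the
structure alone can express.  Instance data travels separately as
:class:`InstanceRecord` objects.

Validation is data, not exceptions: :func:`validate_model` returns every
invariant violation it finds, with coordinates, and an empty report means the
model is accepted by every downstream stage.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field as _field
from enum import Enum
from typing import Union

__all__ = [
    "AtomicKind",
    "FieldKind",
    "Marker",
    "SemanticAnnotation",
    "FieldModel",
    "ClassModel",
    "InstanceRecord",
    "Violation",
    "validate_model",
    "CLASS_LEVEL_MARKERS",
    "FIELD_LEVEL_MARKERS",
    "OBJECT_PROPERTY_ONLY_MARKERS",
]


class AtomicKind(str, Enum):
    """Closed enumeration of scalar field types."""

    STRING = "string"
    INTEGER = "integer"
    DECIMAL = "decimal"
    BOOLEAN = "boolean"
    DATE = "date"
    DATETIME = "datetime"


class FieldKind(str, Enum):
    ATOMIC = "atomic"
    REFERENCE = "reference"
    COLLECTION = "collection"


class Marker(str, Enum):
    """The supported semantic markers and nothing else."""

    EQUIVALENT_CLASS = "EquivalentClass"
    EQUIVALENT_PROPERTY = "EquivalentProperty"
    SYMMETRIC = "Symmetric"
    INVERSE = "Inverse"
    ALL_VALUES_FROM = "AllValuesFrom"
    TRANSITIVE = "Transitive"
    ALL_DIFFERENT = "AllDifferent"
    DIFFERENT_FROM = "DifferentFrom"
    SAME_AS = "SameAs"
    CARDINALITY = "Cardinality"
    MAX_CARDINALITY = "MaxCardinality"
    MIN_CARDINALITY = "MinCardinality"
    SOME_VALUES_FROM = "SomeValuesFrom"


#: Markers legal on a class declaration.
CLASS_LEVEL_MARKERS = frozenset(
    {Marker.EQUIVALENT_CLASS, Marker.SAME_AS, Marker.DIFFERENT_FROM, Marker.ALL_DIFFERENT}
)

#: Markers legal on a field declaration.
FIELD_LEVEL_MARKERS = frozenset(Marker) - CLASS_LEVEL_MARKERS

#: Markers that only make sense on object (reference/collection) fields.
OBJECT_PROPERTY_ONLY_MARKERS = frozenset(
    {Marker.SYMMETRIC, Marker.TRANSITIVE, Marker.INVERSE}
)

#: Markers whose parameter is a non-negative integer.
CARDINALITY_MARKERS = frozenset(
    {Marker.CARDINALITY, Marker.MAX_CARDINALITY, Marker.MIN_CARDINALITY}
)

#: Markers whose parameter is an absolute IRI.
RESOURCE_MARKERS = frozenset(
    {
        Marker.EQUIVALENT_CLASS,
        Marker.EQUIVALENT_PROPERTY,
        Marker.INVERSE,
        Marker.ALL_VALUES_FROM,
        Marker.ALL_DIFFERENT,
        Marker.DIFFERENT_FROM,
        Marker.SAME_AS,
    }
)

#: Markers that take no parameter at all.
PARAMETERLESS_MARKERS = frozenset({Marker.SYMMETRIC, Marker.TRANSITIVE})


@dataclass(frozen=True)
class SemanticAnnotation:
    """One semantic marker with its parameter.

    Which parameter slot is populated depends on the marker: cardinality
    markers carry ``number``, Symmetric/Transitive carry nothing,
    SomeValuesFrom carries ``resource`` XOR ``string_values``, every other
    marker carries ``resource``.  Slot consistency is reported by
    :func:`validate_model`, not enforced at construction, so that malformed
    input documents surface as validation data.
    """

    marker: Marker
    resource: str | None = None
    number: int | None = None
    string_values: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.string_values is not None:
            object.__setattr__(self, "string_values", tuple(self.string_values))

    def slot_errors(self) -> list[str]:
        """Describe any mismatch between the marker and its populated slots."""
        errs = []
        has = {
            "resource": self.resource is not None,
            "number": self.number is not None,
            "string_values": self.string_values is not None,
        }
        if self.marker in CARDINALITY_MARKERS:
            want = {"number"}
        elif self.marker in PARAMETERLESS_MARKERS:
            want = set()
        elif self.marker is Marker.SOME_VALUES_FROM:
            if has["resource"] == has["string_values"]:
                errs.append(
                    f"{self.marker.value} requires exactly one of resource / string_values"
                )
            want = {k for k in ("resource", "string_values") if has[k]}
        else:
            want = {"resource"}
        for slot, populated in has.items():
            if populated and slot not in want:
                errs.append(f"{self.marker.value} does not take a {slot} parameter")
            if not populated and slot in want and self.marker is not Marker.SOME_VALUES_FROM:
                errs.append(f"{self.marker.value} requires a {slot} parameter")
        if self.number is not None and self.number < 0:
            errs.append(f"{self.marker.value} cardinality must be non-negative")
        return errs


# -- convenience constructors mirroring the marker vocabulary ---------------

def EquivalentClass(resource: str) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.EQUIVALENT_CLASS, resource=resource)


def EquivalentProperty(resource: str) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.EQUIVALENT_PROPERTY, resource=resource)


def Symmetric() -> SemanticAnnotation:
    return SemanticAnnotation(Marker.SYMMETRIC)


def Inverse(resource: str) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.INVERSE, resource=resource)


def AllValuesFrom(resource: str) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.ALL_VALUES_FROM, resource=resource)


def Transitive() -> SemanticAnnotation:
    return SemanticAnnotation(Marker.TRANSITIVE)


def AllDifferent(resource: str) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.ALL_DIFFERENT, resource=resource)


def DifferentFrom(resource: str) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.DIFFERENT_FROM, resource=resource)


def SameAs(resource: str) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.SAME_AS, resource=resource)


def Cardinality(number: int) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.CARDINALITY, number=number)


def MaxCardinality(number: int) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.MAX_CARDINALITY, number=number)


def MinCardinality(number: int) -> SemanticAnnotation:
    return SemanticAnnotation(Marker.MIN_CARDINALITY, number=number)


def SomeValuesFrom(
    resource: str | None = None, string_values: list[str] | tuple[str, ...] | None = None
) -> SemanticAnnotation:
    return SemanticAnnotation(
        Marker.SOME_VALUES_FROM,
        resource=resource,
        string_values=tuple(string_values) if string_values is not None else None,
    )


@dataclass(frozen=True)
class FieldModel:
    """One typed field of a source class."""

    name: str
    kind: FieldKind
    atomic_kind: AtomicKind | None = None
    target_class: str | None = None
    is_identifier: bool = False
    annotations: tuple[SemanticAnnotation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "annotations", tuple(self.annotations))


@dataclass(frozen=True)
class ClassModel:
    """One source class: its fields, superclass, and class-level markers."""

    simple_name: str
    qualified_name: str
    superclass: str | None = None
    is_enumeration: bool = False
    enum_literals: tuple[str, ...] = ()
    fields: tuple[FieldModel, ...] = ()
    annotations: tuple[SemanticAnnotation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "enum_literals", tuple(self.enum_literals))
        object.__setattr__(self, "fields", tuple(self.fields))
        object.__setattr__(self, "annotations", tuple(self.annotations))

    def field(self, name: str) -> FieldModel:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(f"{self.simple_name} has no field {name!r}")


AtomicValue = Union[str, int, float, bool]
LocalId = Union[str, int]


@dataclass(frozen=True)
class InstanceRecord:
    """One source object: its class, local identifier, and field values.

    Atomic fields hold scalars (dates as ISO strings or ``datetime`` objects),
    reference fields hold the local id of another record (or an enumeration
    literal when the target class is an enumeration), collection fields hold
    lists thereof.  Absent fields are simply omitted.
    """

    class_name: str
    local_id: LocalId
    values: dict[str, object] = _field(default_factory=dict)


@dataclass(frozen=True)
class Violation:
    """One invariant violation with coordinates into the model or instances."""

    where: str  # e.g. "class Person", "class Person field id", "instance Person/3"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.where}: {self.message}"


def _effective_fields(cls: ClassModel, by_name: dict[str, ClassModel]) -> dict[str, FieldModel]:
    """Own plus inherited fields, walking up the (already checked) chain."""
    out: dict[str, FieldModel] = {}
    seen: set[str] = set()
    cur: ClassModel | None = cls
    while cur is not None and cur.simple_name not in seen:
        seen.add(cur.simple_name)
        for f in cur.fields:
            out.setdefault(f.name, f)
        cur = by_name.get(cur.superclass) if cur.superclass else None
    return out


_PY_ATOMIC_OK = {
    AtomicKind.STRING: (str,),
    AtomicKind.INTEGER: (int,),
    AtomicKind.DECIMAL: (int, float),
    AtomicKind.BOOLEAN: (bool,),
    AtomicKind.DATE: (str, _dt.date),
    AtomicKind.DATETIME: (str, _dt.datetime),
}


def _atomic_value_ok(kind: AtomicKind, value: object) -> bool:
    if isinstance(value, bool) and kind is not AtomicKind.BOOLEAN:
        return False
    return isinstance(value, _PY_ATOMIC_OK[kind])


def validate_model(
    classes: list[ClassModel] | tuple[ClassModel, ...],
    instances: list[InstanceRecord] | tuple[InstanceRecord, ...] = (),
) -> list[Violation]:
    """Check every IR invariant; return one :class:`Violation` per breach.

    The check is idempotent and insensitive to the order of ``classes``;
    an empty report means every downstream operation accepts the model.
    """
    report: list[Violation] = []
    by_name: dict[str, ClassModel] = {}

    for cls in classes:
        where = f"class {cls.simple_name}"
        if cls.simple_name in by_name:
            report.append(Violation(where, "duplicate simple name"))
            continue
        by_name[cls.simple_name] = cls

    for cls in sorted(by_name.values(), key=lambda c: c.simple_name):
        where = f"class {cls.simple_name}"
        if cls.superclass is not None:
            if cls.superclass not in by_name:
                report.append(
                    Violation(where, f"superclass {cls.superclass!r} not in model")
                )
            elif cls.superclass == cls.simple_name:
                report.append(Violation(where, "class cannot extend itself"))
        if cls.is_enumeration:
            if not cls.enum_literals:
                report.append(Violation(where, "enumeration with no literals"))
            if len(set(cls.enum_literals)) != len(cls.enum_literals):
                report.append(Violation(where, "duplicate enumeration literals"))
            if cls.fields:
                report.append(Violation(where, "enumeration must not declare fields"))
            if cls.superclass:
                report.append(Violation(where, "enumeration must not have a superclass"))
        elif cls.enum_literals:
            report.append(Violation(where, "enum_literals set on a non-enumeration"))

        for ann in cls.annotations:
            if ann.marker not in CLASS_LEVEL_MARKERS:
                report.append(
                    Violation(where, f"marker {ann.marker.value} is not class-level")
                )
            for err in ann.slot_errors():
                report.append(Violation(where, err))

        seen_fields: set[str] = set()
        n_ids = 0
        for f in cls.fields:
            fwhere = f"{where} field {f.name}"
            if f.name in seen_fields:
                report.append(Violation(fwhere, "duplicate field name"))
            seen_fields.add(f.name)
            n_ids += f.is_identifier
            if f.kind is FieldKind.ATOMIC:
                if f.atomic_kind is None:
                    report.append(Violation(fwhere, "atomic field without atomic_kind"))
                if f.target_class is not None:
                    report.append(Violation(fwhere, "atomic field with target_class"))
            else:
                if f.target_class is None:
                    report.append(
                        Violation(fwhere, f"{f.kind.value} field without target_class")
                    )
                elif f.target_class not in by_name:
                    report.append(
                        Violation(fwhere, f"target class {f.target_class!r} not in model")
                    )
                if f.atomic_kind is not None:
                    report.append(
                        Violation(fwhere, f"{f.kind.value} field with atomic_kind")
                    )
            for ann in f.annotations:
                if ann.marker not in FIELD_LEVEL_MARKERS:
                    report.append(
                        Violation(fwhere, f"marker {ann.marker.value} is not field-level")
                    )
                for err in ann.slot_errors():
                    report.append(Violation(fwhere, err))
        if n_ids > 1:
            report.append(Violation(where, "more than one identifier field"))

    # cycle check on the inheritance chain
    for cls in sorted(by_name.values(), key=lambda c: c.simple_name):
        seen: set[str] = set()
        cur: ClassModel | None = cls
        while cur is not None and cur.superclass:
            if cur.superclass in seen or cur.superclass == cls.simple_name:
                report.append(
                    Violation(f"class {cls.simple_name}", "inheritance cycle detected")
                )
                break
            seen.add(cur.simple_name)
            cur = by_name.get(cur.superclass)

    # ---- instances -------------------------------------------------------
    ids_by_class: dict[str, set[LocalId]] = {}
    for rec in instances:
        ids_by_class.setdefault(rec.class_name, set())
        rwhere = f"instance {rec.class_name}/{rec.local_id}"
        if rec.local_id in ids_by_class[rec.class_name]:
            report.append(Violation(rwhere, "duplicate local_id for this class"))
        ids_by_class[rec.class_name].add(rec.local_id)

    def _is_subclass(name: str, ancestor: str) -> bool:
        cur = by_name.get(name)
        hops = 0
        while cur is not None and hops <= len(by_name):
            if cur.simple_name == ancestor:
                return True
            cur = by_name.get(cur.superclass) if cur.superclass else None
            hops += 1
        return False

    for rec in instances:
        rwhere = f"instance {rec.class_name}/{rec.local_id}"
        cls = by_name.get(rec.class_name)
        if cls is None:
            report.append(Violation(rwhere, f"unknown class {rec.class_name!r}"))
            continue
        if cls.is_enumeration:
            report.append(Violation(rwhere, "cannot instantiate an enumeration"))
            continue
        eff = _effective_fields(cls, by_name)
        for fname, value in rec.values.items():
            vwhere = f"{rwhere} value {fname}"
            f = eff.get(fname)
            if f is None:
                report.append(Violation(vwhere, "no such field"))
                continue
            if f.kind is FieldKind.ATOMIC:
                if not _atomic_value_ok(f.atomic_kind, value):
                    report.append(
                        Violation(vwhere, f"value {value!r} does not fit {f.atomic_kind.value}")
                    )
            else:
                items = value if f.kind is FieldKind.COLLECTION else [value]
                if f.kind is FieldKind.COLLECTION and not isinstance(value, (list, tuple)):
                    report.append(Violation(vwhere, "collection field needs a list value"))
                    continue
                if f.kind is FieldKind.REFERENCE and isinstance(value, (list, tuple)):
                    report.append(Violation(vwhere, "reference field cannot hold a list"))
                    continue
                target = by_name.get(f.target_class or "")
                for item in items:
                    if target is not None and target.is_enumeration:
                        if item not in target.enum_literals:
                            report.append(
                                Violation(
                                    vwhere,
                                    f"{item!r} is not a literal of {target.simple_name}",
                                )
                            )
                    else:
                        resolved = any(
                            item in ids
                            and _is_subclass(cname, f.target_class or "")
                            for cname, ids in ids_by_class.items()
                        )
                        if not resolved:
                            report.append(
                                Violation(
                                    vwhere,
                                    f"dangling reference {item!r} to {f.target_class}",
                                )
                            )
    return report
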