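"""Front ends that produce the IR.

Two equivalent ways to declare a model:

* **Native classes** — plain Python classes with typed class-level fields.
  Field markers ride on :data:`typing.Annotated` metadata; class-level markers
  are attached with the :func:`semantic` decorator; the identifier field is
  tagged with :data:`ID`; enumerations are :class:`enum.Enum` subclasses.
  :func:`scan_native_model` reflects them into ClassModels at run time.

* **Model documents** — a portable YAML/JSON description validated against a
  published schema (:func:`parse_model_document`).  Both front ends yield the
  identical IR for equivalent declarations.

Instance data is loaded from JSON with :func:`load_instances` and checked
against the model before anything downstream sees it.
"""

from __future__ import annotations

import datetime as _dt
import enum as _enum
import json
import types as _types
import typing
from typing import Annotated, Any, get_args, get_origin, get_type_hints

import pydantic
import yaml

from .model import (
    AtomicKind,
    ClassModel,
    FieldKind,
    FieldModel,
    InstanceRecord,
    Marker,
    SemanticAnnotation,
    Violation,
    validate_model,
)

__all__ = [
    "ID",
    "semantic",
    "scan_native_model",
    "render_native_model",
    "parse_model_document",
    "dump_model_document",
    "load_instances",
    "IntrospectionError",
    "DocumentError",
    "InstanceError",
    "model_document_schema",
    "instance_document_schema",
]


class IntrospectionError(ValueError):
    """A native class cannot be reflected into the IR."""


class DocumentError(ValueError):
    """A model/instance document violates its schema."""


class InstanceError(ValueError):
    """Instance records do not fit the model."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("; ".join(map(str, violations)))


class _IdMarker:
    """Sentinel placed in Annotated metadata to flag the identifier field."""

    def __repr__(self) -> str:  # pragma: no cover
        return "ID"


#: Tag for the identifier field: ``id: Annotated[int, ID]``.
ID = _IdMarker()


def semantic(*annotations: SemanticAnnotation):
    """Class decorator attaching class-level semantic markers.

    Example::

        @semantic(EquivalentClass("http://cz.zcu.kiv/TestedSubject"))
        class Person: ...
    """

    def deco(cls):
        for ann in annotations:
            if not isinstance(ann, SemanticAnnotation):
                raise IntrospectionError(
                    f"@semantic on {cls.__name__}: {ann!r} is not a semantic marker"
                )
        cls.__semantic_annotations__ = tuple(annotations)
        return cls

    return deco


_ATOMIC_BY_PYTYPE: dict[type, AtomicKind] = {
    str: AtomicKind.STRING,
    int: AtomicKind.INTEGER,
    float: AtomicKind.DECIMAL,
    bool: AtomicKind.BOOLEAN,
    _dt.date: AtomicKind.DATE,
    _dt.datetime: AtomicKind.DATETIME,
}
_PYTYPE_BY_ATOMIC = {
    AtomicKind.STRING: str,
    AtomicKind.INTEGER: int,
    AtomicKind.DECIMAL: float,
    AtomicKind.BOOLEAN: bool,
    AtomicKind.DATE: _dt.date,
    AtomicKind.DATETIME: _dt.datetime,
}


def _collect_classes(source) -> list[type]:
    if isinstance(source, _types.ModuleType):
        return [
            obj
            for obj in vars(source).values()
            if isinstance(obj, type) and obj.__module__ == source.__name__
        ]
    return list(source)


def _scan_field(
    cls: type, name: str, hint: Any, class_names: set[str]
) -> FieldModel:
    where = f"{cls.__name__}.{name}"
    markers: list[SemanticAnnotation] = []
    is_id = False
    if get_origin(hint) is Annotated:
        hint, *meta = get_args(hint)
        for m in meta:
            if isinstance(m, SemanticAnnotation):
                markers.append(m)
            elif isinstance(m, _IdMarker):
                is_id = True
            else:
                raise IntrospectionError(
                    f"{where}: unsupported field metadata {m!r}"
                )
    origin = get_origin(hint)
    if origin in (list, tuple, typing.List):
        (elem,) = get_args(hint) or (None,)
        if isinstance(elem, type) and elem.__name__ in class_names:
            return FieldModel(
                name,
                FieldKind.COLLECTION,
                target_class=elem.__name__,
                is_identifier=is_id,
                annotations=tuple(markers),
            )
        raise IntrospectionError(
            f"{where}: collections must hold a scanned model class, got {elem!r}"
        )
    if origin is not None:
        raise IntrospectionError(f"{where}: unsupported type construct {hint!r}")
    if isinstance(hint, type) and hint.__name__ in class_names and hint not in _ATOMIC_BY_PYTYPE:
        return FieldModel(
            name,
            FieldKind.REFERENCE,
            target_class=hint.__name__,
            is_identifier=is_id,
            annotations=tuple(markers),
        )
    # datetime.datetime subclasses datetime.date: check the exact type first
    kind = _ATOMIC_BY_PYTYPE.get(hint)
    if kind is None:
        raise IntrospectionError(f"{where}: unresolved field type {hint!r}")
    return FieldModel(
        name,
        FieldKind.ATOMIC,
        atomic_kind=kind,
        is_identifier=is_id,
        annotations=tuple(markers),
    )


def scan_native_model(source) -> list[ClassModel]:
    """Reflect native Python classes into the IR.

    ``source`` is a module (every class defined in it is scanned) or an
    explicit iterable of classes.  Typed class-level fields become
    FieldModels in declaration order; ``Annotated`` metadata carries field
    markers and the :data:`ID` tag; Enum subclasses become enumerations.
    """
    classes = _collect_classes(source)
    class_names = {c.__name__ for c in classes}
    by_type = {c.__name__: c for c in classes}
    localns = dict(by_type)
    out: list[ClassModel] = []
    for cls in classes:
        qualified = f"{cls.__module__}.{cls.__qualname__}"
        superclass = None
        for base in cls.__bases__:
            if base is object or (isinstance(base, type) and issubclass(base, _enum.Enum)):
                continue
            if base.__name__ in class_names:
                if superclass is not None:
                    raise IntrospectionError(
                        f"{cls.__name__}: multiple model superclasses are not supported"
                    )
                superclass = base.__name__
            elif not issubclass(cls, _enum.Enum):
                raise IntrospectionError(
                    f"{cls.__name__}: superclass {base.__name__} is not part of the model"
                )
        class_markers = tuple(getattr(cls, "__semantic_annotations__", ()))
        # attribute is inherited; only count it on the class that declared it
        if "__semantic_annotations__" not in cls.__dict__:
            class_markers = ()
        if isinstance(cls, type) and issubclass(cls, _enum.Enum):
            out.append(
                ClassModel(
                    simple_name=cls.__name__,
                    qualified_name=qualified,
                    is_enumeration=True,
                    enum_literals=tuple(m.name for m in cls),
                    annotations=class_markers,
                )
            )
            continue
        own = dict(cls.__dict__.get("__annotations__", {}))
        try:
            hints = get_type_hints(cls, localns=localns, include_extras=True)
        except Exception as exc:
            raise IntrospectionError(f"{cls.__name__}: cannot resolve field types: {exc}")
        fields = tuple(
            _scan_field(cls, name, hints[name], class_names) for name in own
        )
        out.append(
            ClassModel(
                simple_name=cls.__name__,
                qualified_name=qualified,
                superclass=superclass,
                fields=fields,
                annotations=class_markers,
            )
        )
    return out


def render_native_model(
    classes: list[ClassModel], module_name: str | None = None
) -> list[type]:
    """Materialize the IR back into native Python classes.

    The inverse of :func:`scan_native_model` up to IR equality: scanning the
    rendered classes reproduces the input model exactly.  Used for
    round-trip testing and as an executable record of the native idiom.
    """
    by_name = {c.simple_name: c for c in classes}
    built: dict[str, type] = {}

    def build_class(name: str) -> type:
        # phase 1: bare classes in superclass order (chains are acyclic)
        if name in built:
            return built[name]
        cm = by_name[name]
        module, _, _ = cm.qualified_name.rpartition(".")
        if module_name is not None:
            module = module_name
        if cm.is_enumeration:
            cls = _enum.Enum(cm.simple_name, [(lit, lit) for lit in cm.enum_literals])
        else:
            base = build_class(cm.superclass) if cm.superclass else object
            cls = type(cm.simple_name, (base,), {"__annotations__": {}})
        cls.__module__ = module
        cls.__qualname__ = cm.simple_name
        if cm.annotations:
            cls.__semantic_annotations__ = tuple(cm.annotations)
        built[name] = cls
        return cls

    for c in classes:
        build_class(c.simple_name)

    # phase 2: fill field annotations; references may now point anywhere,
    # including back at the declaring class
    for cm in classes:
        if cm.is_enumeration:
            continue
        anns: dict[str, Any] = {}
        for f in cm.fields:
            if f.kind is FieldKind.ATOMIC:
                py: Any = _PYTYPE_BY_ATOMIC[f.atomic_kind]
            elif f.kind is FieldKind.REFERENCE:
                py = built[f.target_class]
            else:
                py = list[built[f.target_class]]
            meta = list(f.annotations)
            if f.is_identifier:
                meta.insert(0, ID)
            if meta:
                py = Annotated[tuple([py] + meta)]
            anns[f.name] = py
        built[cm.simple_name].__annotations__.update(anns)

    return [built[c.simple_name] for c in classes]


# ---------------------------------------------------------------------------
# model documents (YAML / JSON)
# ---------------------------------------------------------------------------

_MARKER_NAMES = {m.value for m in Marker}
_ATOMIC_NAMES = {k.value for k in AtomicKind}


class _AnnotationDoc(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    marker: str
    resource: str | None = None
    number: int | None = None
    string_values: list[str] | None = None

    @pydantic.field_validator("marker")
    @classmethod
    def _known_marker(cls, v: str) -> str:
        if v not in _MARKER_NAMES:
            raise ValueError(f"unknown marker {v!r}; expected one of {sorted(_MARKER_NAMES)}")
        return v

    def to_ir(self) -> SemanticAnnotation:
        return SemanticAnnotation(
            Marker(self.marker),
            resource=self.resource,
            number=self.number,
            string_values=tuple(self.string_values) if self.string_values is not None else None,
        )


class _FieldDoc(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    name: str
    type: str
    collection: bool = False
    id: bool = False
    annotations: list[_AnnotationDoc] = []


class _ClassDoc(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    name: str
    package: str
    extends: str | None = None
    enum: list[str] | None = None
    fields: list[_FieldDoc] = []
    annotations: list[_AnnotationDoc] = []


class _ModelDoc(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    classes: list[_ClassDoc]


class _InstanceDoc(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    # "class" is a Python keyword; documents use it verbatim
    class_: str = pydantic.Field(alias="class")
    id: str | int
    values: dict[str, Any] = {}


class _InstancesDoc(pydantic.RootModel):
    root: list[_InstanceDoc]


def model_document_schema() -> dict:
    """JSON Schema for the portable model-description document."""
    return _ModelDoc.model_json_schema()


def instance_document_schema() -> dict:
    """JSON Schema for the instance document."""
    return _InstancesDoc.model_json_schema()


def parse_model_document(text: str, format: str = "yaml") -> list[ClassModel]:
    """Parse a YAML/JSON model document into the IR.

    Yields exactly the IR :func:`scan_native_model` produces for the
    equivalent native declaration.
    """
    fmt = format.lower()
    if fmt == "yaml":
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise DocumentError(f"not valid YAML: {exc}")
    elif fmt == "json":
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise DocumentError(f"not valid JSON: {exc}")
    else:
        raise DocumentError(f"unknown document format {format!r} (yaml or json)")
    if raw is None:
        raw = {"classes": []}
    try:
        doc = _ModelDoc.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise DocumentError(str(exc))

    out: list[ClassModel] = []
    class_names = {c.name for c in doc.classes}
    for c in doc.classes:
        if c.enum is not None:
            out.append(
                ClassModel(
                    simple_name=c.name,
                    qualified_name=f"{c.package}.{c.name}",
                    is_enumeration=True,
                    enum_literals=tuple(c.enum),
                    annotations=tuple(a.to_ir() for a in c.annotations),
                )
            )
            continue
        fields = []
        for f in c.fields:
            anns = tuple(a.to_ir() for a in f.annotations)
            if f.type in _ATOMIC_NAMES:
                if f.collection:
                    raise DocumentError(
                        f"classes/{c.name}/fields/{f.name}: collections of atomic "
                        f"type {f.type!r} are not supported"
                    )
                fields.append(
                    FieldModel(
                        f.name,
                        FieldKind.ATOMIC,
                        atomic_kind=AtomicKind(f.type),
                        is_identifier=f.id,
                        annotations=anns,
                    )
                )
            elif f.type in class_names:
                fields.append(
                    FieldModel(
                        f.name,
                        FieldKind.COLLECTION if f.collection else FieldKind.REFERENCE,
                        target_class=f.type,
                        is_identifier=f.id,
                        annotations=anns,
                    )
                )
            else:
                raise DocumentError(
                    f"classes/{c.name}/fields/{f.name}: type {f.type!r} is neither "
                    f"an atomic kind nor a class in this document"
                )
        out.append(
            ClassModel(
                simple_name=c.name,
                qualified_name=f"{c.package}.{c.name}",
                superclass=c.extends,
                fields=tuple(fields),
                annotations=tuple(a.to_ir() for a in c.annotations),
            )
        )
    return out


def dump_model_document(classes: list[ClassModel]) -> str:
    """Render the IR as a YAML model document (inverse of parsing)."""
    doc: dict[str, Any] = {"classes": []}
    for c in classes:
        package, _, _ = c.qualified_name.rpartition(".")
        entry: dict[str, Any] = {"name": c.simple_name, "package": package}
        if c.superclass:
            entry["extends"] = c.superclass
        if c.is_enumeration:
            entry["enum"] = list(c.enum_literals)
        if c.fields:
            entry["fields"] = []
            for f in c.fields:
                fe: dict[str, Any] = {
                    "name": f.name,
                    "type": f.atomic_kind.value if f.kind is FieldKind.ATOMIC else f.target_class,
                }
                if f.kind is FieldKind.COLLECTION:
                    fe["collection"] = True
                if f.is_identifier:
                    fe["id"] = True
                if f.annotations:
                    fe["annotations"] = [_ann_to_doc(a) for a in f.annotations]
                entry["fields"].append(fe)
        if c.annotations:
            entry["annotations"] = [_ann_to_doc(a) for a in c.annotations]
        doc["classes"].append(entry)
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def _ann_to_doc(a: SemanticAnnotation) -> dict[str, Any]:
    d: dict[str, Any] = {"marker": a.marker.value}
    if a.resource is not None:
        d["resource"] = a.resource
    if a.number is not None:
        d["number"] = a.number
    if a.string_values is not None:
        d["string_values"] = list(a.string_values)
    return d


def load_instances(text: str, model: list[ClassModel]) -> list[InstanceRecord]:
    """Load a JSON instance document and validate it against the model.

    Raises :class:`InstanceError` carrying every per-record violation.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DocumentError(f"not valid JSON: {exc}")
    try:
        doc = _InstancesDoc.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise DocumentError(str(exc))
    records = [
        InstanceRecord(class_name=r.class_, local_id=r.id, values=dict(r.values))
        for r in doc.root
    ]
    model_problems = validate_model(model)
    if model_problems:
        raise InstanceError(model_problems)
    violations = [
        v for v in validate_model(model, records) if v.where.startswith("instance")
    ]
    if violations:
        raise InstanceError(violations)
    return records
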