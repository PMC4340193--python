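# Methods

## The model and its assumptions

`owlbind` maps an annotated object model to an OWL ontology in three stages,
each a pure function over an explicit intermediate representation (IR).

**IR.** A model is a list of `ClassModel` values: simple name, qualified
source name, optional single superclass, either an enumeration (a closed list
of literals) or a list of typed fields. A field is atomic (string, integer,
decimal, boolean, date, datetime), a reference to another model class, or a
collection of such references. Collections of atomics are rejected: a
repeated scalar has no counterpart among the emitted property shapes, and no
supported declaration form produces one. At most one field per class may be
flagged as the identifier; its only role is individual naming (below).
Semantic markers attach to classes (`EquivalentClass`, `SameAs`,
`DifferentFrom`, `AllDifferent`) or to fields (the remaining nine). The IR is
produced either by run-time reflection of native Python classes — typed
class-level attributes, `typing.Annotated` metadata for markers, `Enum`
subclasses for enumerations — or by parsing a YAML/JSON model document
validated against the shipped schemas (pydantic models, exported as JSON
Schema under `src/owlbind/data/`). Both front ends yield identical IR for
equivalent declarations, and `render_native_model` inverts the scan, which is
checked by a generative property test.

**Structural mapping.** Each class becomes an `owl:Class` carrying its
qualified source name on a framework annotation property
(`semantic:javaclass` by default; both namespace and local name are
configurable). Inheritance becomes `rdfs:subClassOf` between the direct
parent and child only — the transitive closure is the reasoner's job, not the
emitter's. Fields become properties. Because OWL properties are global while
fields belong to a class, equally named fields are merged: identical ranges
yield one property whose `rdfs:domain` is an `owl:unionOf` over the declaring
classes; conflicting ranges (different datatypes, different target classes,
or datatype vs. object) are a hard `MappingError` — silent merging would
corrupt the ontology undetectably. Inherited fields are mapped once, on the
declaring class; subclasses see them through `rdfs:subClassOf`. Enumerations
become a class equivalent to an anonymous class whose `owl:oneOf` lists one
named individual per literal (`Gender_MALE`, ...), each also typed by the
enumeration class.

**Instance mapping.** Each record becomes a named individual typed by its
class. Naming is sequential by default — `Person_0`, `Person_1`, ... in
record order, per class — or taken from the identifier field's value
(`individual_naming="identifier-field"`), which requires passing the class
models since the identifier flag is IR metadata not present in the graph. All
individual IRIs are minted before any assertion is emitted, so mutually
referencing records (cycles) resolve without duplication. Atomic values
become literals typed by the property's declared range; reference values
name another record's local id (or an enumeration literal when the target is
an enumeration); absent fields are simply omitted — no assertion, no null
placeholder.

**Semantic mapping.** Each marker adds exactly one construct:
`owl:equivalentClass`, `owl:equivalentProperty`, `owl:sameAs`,
`owl:differentFrom`, `rdf:type` of the referenced resource (`AllDifferent`,
emitted exactly in that bare form — no `owl:distinctMembers` list, matching
the documented mapping table), `rdf:type owl:SymmetricProperty` /
`owl:TransitiveProperty`, `owl:inverseOf`, or an anonymous `owl:Restriction`
attached as `rdfs:subClassOf` of the *declaring* class with `owl:onProperty`
pointing at the field's property. Symmetric/Transitive/Inverse on an atomic
field is an error: OWL defines these only for object properties.
`SameAs`/`DifferentFrom`/`AllDifferent` are accepted at class level even
though OWL-DL prefers them on individuals; the tool emits what the marker
says rather than second-guessing the modeler.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| `base_iri` | `http://owlbind.dev/model#` | namespace for minted classes/properties/individuals; a trailing `#` or `/` is required (appended if missing) |
| `source_annotation_local_name` | `javaclass` | the conventional name for the source-class annotation property |
| `cardinality_datatype` | `xsd:int` | cardinality restriction literals conventionally use `xsd:int`, while integer field ranges use `xsd:integer`; both conventions are kept and each is configurable |
| `individual_naming` | `sequential` | `Class_k` from 0, deterministic in record order |

The `SomeValuesFrom` marker has two forms: a resource IRI (plain
`owl:someValuesFrom <iri>`) and `string_values`, which builds an
`owl:DataRange` whose `owl:oneOf` is an RDF list of `xsd:string` literals.
The string form emits its values as plain string literals even when they look
like URIs — the value set is a set of strings by declaration, and rewriting
them into IRIs would change the modeler's statement.

## Numerical and determinism choices

Blank nodes (restrictions, union domains, data ranges, list cells) carry
labels derived deterministically from the model element they describe, e.g.
`restriction_Person_dateofBirth_Cardinality`. This makes `apply_semantics`
idempotent by plain set semantics (re-running adds the same triples to a
triple set) and makes serialization reproducible byte-for-byte across runs.
Blank-node labels are *not* part of the document contract: equality of
ontology documents is graph isomorphism, checked with `rdflib.compare`.

Serialization goes through rdflib. Five syntaxes are exposed: `rdfxml`,
`rdfxml-abbrev`, `turtle`, `ntriples`, `n3`; `supported_syntaxes()` is the
capability query. The abbreviated RDF/XML writer is a thin subclass of
rdflib's pretty-printer that writes RDF list cells as explicit
`rdf:first`/`rdf:rest` descriptions instead of `rdf:parseType="Collection"`,
because the Collection form cannot carry literal list items and would
silently turn the DataRange's string members into resources on parse-back.
Every syntax is covered by a round-trip isomorphism test, pairwise across
syntaxes.

IRI minting is injective by construction within a run
(`base#Name` / `base#field` / `base#Class_k`); the one collision the scheme
allows — a field named identically to a class — is detected and raised
rather than silently punned.

## The bundled fixture

`owlbind.eeg` ships an EEG/ERP experiment-metadata model: one class per
semantic group (Activity, Environment, Person, HardwareEquipment,
SoftwareEquipment, Electrode, DataDigitalization, SignalAnalysis,
DataPresentation, SignalArtifact), hub classes Experiment/Scenario/Data, a
ResearchGroup class, and a Gender enumeration. Person carries the complete
marker vocabulary, including an equivalence to an external `TestedSubject`
class, a value constraint on `firstname`, exact cardinality 1 on
`dateofBirth`, and minimum cardinality 1 on `researchGroups`. The same model
ships as a YAML model document (`data/eeg_model.yaml`), and a test asserts
the two forms parse to the same IR.

`generate_instances(n, seed)` emulates a metadata store dump: n Experiment
records, each linked to one fresh Person, Scenario, HardwareEquipment and
Data record — 5n records of constant shape, with attribute values drawn from
small synthetic pools by `random.Random(seed)`. Constant shape makes the
mapped triple count exactly affine in n, `count(n) = a + b·n`, which the
tests verify at n ∈ {1, 2, 5, 10} by fitting (a, b) at n = 1, 2 and
predicting n = 5, 10; a soft wall-clock check at n ∈ {100, 200, 400}
confirms sub-quadratic growth. These sizes keep the whole suite under a few
seconds while still separating linear from quadratic behaviour.

What the generator does **not** emulate: real names or hardware inventories,
variable per-experiment record shapes, shared sub-records (two experiments
using the same hardware), missing-value patterns, or real EEG signal data.
Passing tests therefore demonstrate the mapping and serialization machinery,
not robustness to messy production metadata.

## Known limitations

* Single inheritance only; no generic types beyond single-element
  collections; no method/behaviour modeling.
* No reasoning or consistency checking; `owl:intersectionOf`/`complementOf`
  have no marker and are never emitted.
* Union-domain merging covers equally named fields with equal ranges only;
  deliberate property polymorphism is unsupported (hard error).
* The native scanner reads class-level type annotations only;
  property-style accessors are invisible to it by design.
* OWL/XML and N3 sub-dialect outputs are not offered.
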