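"""EEG/ERP experiment-metadata model and a seeded instance generator.

Electrophysiology experiments are described by metadata falling into ten
semantic groups — the experimental protocol (Activity), ambient conditions
(Environment), the tested subject (Person), hardware and software equipment,
the electrodes used, data digitalization parameters, signal-analysis steps,
presentation of results, and signal artifacts — plus hub records: an
Experiment ties one Person, one Scenario, one HardwareEquipment and one Data
record together.

The Person class carries the full supported marker vocabulary (equivalence,
sameness/difference, property character, value and cardinality constraints),
so mapping this model exercises every semantic construct the mapper emits.

All attribute *values* produced by :func:`generate_instances` are synthetic:
drawn from small hand-written pools by a seeded PRNG.  Only the schema and
the per-experiment linkage shape are domain-constrained.
"""

from __future__ import annotations

import random
from importlib import resources

from .model import (
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
    MaxCardinality,
    MinCardinality,
    SameAs,
    SomeValuesFrom,
    Symmetric,
    Transitive,
)

__all__ = [
    "build_domain_model",
    "generate_instances",
    "model_document",
    "SEMANTIC_GROUPS",
    "PACKAGE",
]


def model_document() -> str:
    """The same model in its portable YAML form (shipped with the package)."""
    return (
        resources.files("owlbind").joinpath("data/eeg_model.yaml").read_text("utf-8")
    )

PACKAGE = "cz.zcu.kiv"

#: The ten metadata groups, one class each.
SEMANTIC_GROUPS = (
    "Activity",
    "Environment",
    "Person",
    "HardwareEquipment",
    "SoftwareEquipment",
    "Electrode",
    "DataDigitalization",
    "SignalAnalysis",
    "DataPresentation",
    "SignalArtifact",
)


def _atomic(name: str, kind: AtomicKind, *, is_id: bool = False, annotations=()) -> FieldModel:
    return FieldModel(
        name, FieldKind.ATOMIC, atomic_kind=kind, is_identifier=is_id,
        annotations=tuple(annotations),
    )


def _ref(name: str, target: str, *, annotations=()) -> FieldModel:
    return FieldModel(
        name, FieldKind.REFERENCE, target_class=target, annotations=tuple(annotations)
    )


def _coll(name: str, target: str, *, annotations=()) -> FieldModel:
    return FieldModel(
        name, FieldKind.COLLECTION, target_class=target, annotations=tuple(annotations)
    )


def _id() -> FieldModel:
    return _atomic("id", AtomicKind.INTEGER, is_id=True)


def build_domain_model() -> list[ClassModel]:
    """The experiment-metadata model: ten semantic groups plus hub classes."""

    def cm(name: str, fields, annotations=(), superclass=None) -> ClassModel:
        return ClassModel(
            simple_name=name,
            qualified_name=f"{PACKAGE}.{name}",
            superclass=superclass,
            fields=tuple(fields),
            annotations=tuple(annotations),
        )

    gender = ClassModel(
        simple_name="Gender",
        qualified_name=f"{PACKAGE}.Gender",
        is_enumeration=True,
        enum_literals=("MALE", "FEMALE"),
    )

    person = cm(
        "Person",
        [
            _id(),
            _atomic(
                "firstname",
                AtomicKind.STRING,
                annotations=[SomeValuesFrom(string_values=["http://cz.zcu.kiv/GivenNames"])],
            ),
            _atomic(
                "lastname",
                AtomicKind.STRING,
                annotations=[EquivalentProperty("http://www.kiv.zcu.cz/first_name")],
            ),
            _atomic("dateofBirth", AtomicKind.DATE, annotations=[Cardinality(1)]),
            _coll("researchGroups", "ResearchGroup", annotations=[MinCardinality(1)]),
            _coll("colleagues", "Person", annotations=[Symmetric()]),
            _ref("supervisor", "Person", annotations=[Inverse("http://cz.zcu.kiv/supervises")]),
            _coll("ancestors", "Person", annotations=[Transitive()]),
            _coll(
                "experiments",
                "Experiment",
                annotations=[AllValuesFrom("http://cz.zcu.kiv/Experiment")],
            ),
            _atomic("phoneNumber", AtomicKind.STRING, annotations=[MaxCardinality(1)]),
            _ref("gender", "Gender"),
            _atomic("laterality", AtomicKind.STRING),
            _atomic("education", AtomicKind.STRING),
        ],
        annotations=[
            EquivalentClass("http://cz.zcu.kiv/TestedSubject"),
            SameAs("http://cz.zcu.kiv/Subject"),
            DifferentFrom("http://cz.zcu.kiv/Experimenter"),
            AllDifferent("http://www.kiv.zcu.cz/#AllDifferent"),
        ],
    )

    return [
        cm(
            "Experiment",
            [
                _id(),
                _atomic("startTime", AtomicKind.DATETIME),
                _atomic("temperature", AtomicKind.DECIMAL),
                _ref("person", "Person"),
                _ref("scenario", "Scenario"),
                _ref("hardware", "HardwareEquipment"),
                _ref("data", "Data"),
            ],
        ),
        person,
        gender,
        cm("ResearchGroup", [_id(), _atomic("title", AtomicKind.STRING)]),
        cm(
            "Scenario",
            [_id(), _atomic("title", AtomicKind.STRING),
             _atomic("description", AtomicKind.STRING)],
        ),
        cm(
            "Data",
            [_id(), _atomic("filename", AtomicKind.STRING),
             _atomic("samplingRate", AtomicKind.DECIMAL)],
        ),
        cm(
            "Activity",
            [_id(), _atomic("stimulation", AtomicKind.STRING),
             _atomic("instructions", AtomicKind.STRING)],
        ),
        cm(
            "Environment",
            [_id(), _atomic("weather", AtomicKind.STRING),
             _atomic("roomTemperature", AtomicKind.DECIMAL),
             _atomic("daytime", AtomicKind.STRING)],
        ),
        cm(
            "HardwareEquipment",
            [_id(), _atomic("type", AtomicKind.STRING),
             _atomic("producer", AtomicKind.STRING),
             _atomic("serialNumber", AtomicKind.STRING)],
        ),
        cm(
            "SoftwareEquipment",
            [_id(), _atomic("name", AtomicKind.STRING),
             _atomic("version", AtomicKind.STRING)],
        ),
        cm(
            "Electrode",
            [_id(), _atomic("electrodeType", AtomicKind.STRING),
             _atomic("impedance", AtomicKind.DECIMAL),
             _atomic("location", AtomicKind.STRING)],
        ),
        cm(
            "DataDigitalization",
            [_id(), _atomic("filtration", AtomicKind.STRING),
             _atomic("samplingFrequency", AtomicKind.DECIMAL)],
        ),
        cm(
            "SignalAnalysis",
            [_id(), _atomic("preStimulusMs", AtomicKind.INTEGER),
             _atomic("postStimulusMs", AtomicKind.INTEGER),
             _atomic("epochCount", AtomicKind.INTEGER)],
        ),
        cm(
            "DataPresentation",
            [_id(), _atomic("averagedWaves", AtomicKind.STRING),
             _atomic("rawDataLink", AtomicKind.STRING)],
        ),
        cm(
            "SignalArtifact",
            [_id(), _atomic("compensationMethod", AtomicKind.STRING),
             _atomic("rejectionCondition", AtomicKind.STRING)],
        ),
    ]


# synthetic value pools (invented fixture content)
_FIRSTNAMES = ("Jan", "Petr", "Eva", "Marie", "Tomas", "Lucie")
_LASTNAMES = ("Novak", "Svoboda", "Dvorak", "Cerna", "Prochazka")
_SCENARIOS = ("Auditory oddball", "Visual P300", "N400 priming", "Resting state")
_HW_TYPES = ("amplifier", "electrode cap", "stimulator")
_PRODUCERS = ("BrainProducts", "g.tec", "Neuroscan")
_RATES = (250.0, 500.0, 1000.0)


def generate_instances(n: int, seed: int = 0) -> list[InstanceRecord]:
    """Generate ``n`` Experiment records, each linked to one fresh Person,
    Scenario, HardwareEquipment and Data record (``5 * n`` records total).

    Deterministic for a fixed seed; every record has the same shape, so the
    triple count of the mapped graph is exactly affine in ``n``.
    """
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    rng = random.Random(seed)
    records: list[InstanceRecord] = []
    for k in range(n):
        pid, sid, hid, did = f"p{k}", f"s{k}", f"h{k}", f"d{k}"
        records.append(
            InstanceRecord(
                "Person",
                pid,
                {
                    "id": k,
                    "firstname": rng.choice(_FIRSTNAMES),
                    "lastname": rng.choice(_LASTNAMES),
                    "dateofBirth": f"19{rng.randint(50, 99)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}",
                    "gender": rng.choice(("MALE", "FEMALE")),
                    "laterality": rng.choice(("left", "right")),
                },
            )
        )
        records.append(
            InstanceRecord(
                "Scenario",
                sid,
                {"id": k, "title": rng.choice(_SCENARIOS),
                 "description": f"synthetic scenario {k}"},
            )
        )
        records.append(
            InstanceRecord(
                "HardwareEquipment",
                hid,
                {"id": k, "type": rng.choice(_HW_TYPES),
                 "producer": rng.choice(_PRODUCERS),
                 "serialNumber": f"SN-{rng.randint(10000, 99999)}"},
            )
        )
        records.append(
            InstanceRecord(
                "Data",
                did,
                {"id": k, "filename": f"experiment_{k}.eeg",
                 "samplingRate": rng.choice(_RATES)},
            )
        )
        records.append(
            InstanceRecord(
                "Experiment",
                f"e{k}",
                {
                    "id": k,
                    "startTime": f"2013-0{rng.randint(1, 9)}-{rng.randint(1, 28):02d}T{rng.randint(8, 17):02d}:00:00",
                    "temperature": round(rng.uniform(18.0, 26.0), 1),
                    "person": pid,
                    "scenario": sid,
                    "hardware": hid,
                    "data": did,
                },
            )
        )
    return records
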