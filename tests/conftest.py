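import datetime
from typing import Annotated

import pytest

from owlbind import (
    ID,
    Cardinality,
    EquivalentClass,
    MappingConfig,
    MinCardinality,
    SomeValuesFrom,
    scan_native_model,
    semantic,
)
from owlbind.eeg import build_domain_model, generate_instances

BASE = "http://cz.zcu.kiv/ontology#"


@pytest.fixture
def cfg():
    return MappingConfig(base_iri=BASE)


def make_person_model():
    """The plain Person/ResearchGroup worked example as native classes."""

    class ResearchGroup:
        pass

    class Person:
        id: Annotated[int, ID]
        firstname: str
        researchGroups: list[ResearchGroup]

    for cls in (Person, ResearchGroup):
        cls.__module__ = "cz.zcu.kiv"
        cls.__qualname__ = cls.__name__
    return scan_native_model([Person, ResearchGroup])


def make_annotated_person_model():
    """The annotated Person worked example as native classes."""

    class ResearchGroup:
        pass

    @semantic(EquivalentClass("http://cz.zcu.kiv/TestedSubject"))
    class Person:
        id: Annotated[int, ID]
        firstname: Annotated[
            str, SomeValuesFrom(string_values=["http://cz.zcu.kiv/GivenNames"])
        ]
        dateofBirth: Annotated[datetime.date, Cardinality(1)]
        researchGroups: Annotated[list[ResearchGroup], MinCardinality(1)]

    for cls in (Person, ResearchGroup):
        cls.__module__ = "cz.zcu.kiv"
        cls.__qualname__ = cls.__name__
    return scan_native_model([Person, ResearchGroup])


@pytest.fixture
def person_model():
    return make_person_model()


@pytest.fixture
def annotated_person_model():
    return make_annotated_person_model()


@pytest.fixture(scope="session")
def eeg_model():
    return build_domain_model()


@pytest.fixture(scope="session")
def eeg_instances():
    return generate_instances(3, seed=42)
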