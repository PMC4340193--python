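# owlbind

Code-first OWL ontology generation from annotated object models.

Research software that keeps its data in ordinary object-oriented classes
backed by a relational store — a neurophysiology metadata portal, a LIMS, any
domain system built from plain data classes — often needs to publish that
content as an OWL ontology so that semantic registries and reasoners can
consume it. Hand-maintaining a parallel ontology drifts out of sync with the
code. `owlbind` instead treats the class declarations themselves as the
ontology source: it reflects typed classes (or a portable YAML/JSON model
description) into an intermediate representation, maps structure and
instances to OWL, applies semantic enrichment markers attached to the
declarations, and serializes the result in several RDF syntaxes.

## The mapping

For a set of source classes $\{J_i\}$ with typed fields $\{Jf_{ij}\}$ the
emitted ontology $O$ satisfies:

* every class $J_i$ has an `owl:Class` $OC_i \in O$, annotated with its
  fully qualified source name via a framework annotation property
  (`semantic:javaclass`);
* inheritance maps to `rdfs:subClassOf`;
* an atomic field becomes an `owl:DatatypeProperty` with `rdfs:domain` the
  declaring class and `rdfs:range` the matching XSD datatype; a field typed
  by another class (or a list of one) becomes an `owl:ObjectProperty`;
* enumerations become classes equivalent to an `owl:oneOf` list of
  individuals;
* every instance record becomes a named individual (`Person_0`, `Person_1`,
  ...) typed by its class, with literal and object-property assertions
  $OL_{ij} \simeq Jf_{ij}$.

Semantic markers carried by the declarations add constructs the structure
alone cannot express: `EquivalentClass`/`EquivalentProperty`, `SameAs`,
`DifferentFrom`, `AllDifferent`, `Symmetric`, `Transitive`, `Inverse`, and
the property restrictions `AllValuesFrom`, `SomeValuesFrom`, `Cardinality`,
`MaxCardinality`, `MinCardinality`. Restrictions are emitted as anonymous
`owl:Restriction` superclasses of the declaring class, e.g. `@Cardinality(1)`
on `dateofBirth` yields

```xml
<rdfs:subClassOf>
  <owl:Restriction>
    <owl:onProperty rdf:resource="#dateofBirth"/>
    <owl:cardinality rdf:datatype="&xsd;int">1</owl:cardinality>
  </owl:Restriction>
</rdfs:subClassOf>
```

A bundled EEG/ERP experiment-metadata model (ten semantic groups —
experimental protocol, environment, tested subject, hardware, software,
electrodes, digitalization, signal analysis, data presentation, artifacts —
plus Experiment/Scenario/Data hub classes) and a seeded instance generator
make the whole pipeline runnable with no external data.

## Worked example

```python
import datetime
from typing import Annotated
from owlbind import (
    ID, Cardinality, EquivalentClass, MinCardinality, SomeValuesFrom,
    semantic, scan_native_model, map_structure, apply_semantics, serialize,
)

class ResearchGroup:
    pass

@semantic(EquivalentClass("http://cz.zcu.kiv/TestedSubject"))
class Person:
    id: Annotated[int, ID]
    firstname: Annotated[str, SomeValuesFrom(string_values=["http://cz.zcu.kiv/GivenNames"])]
    dateofBirth: Annotated[datetime.date, Cardinality(1)]
    researchGroups: Annotated[list[ResearchGroup], MinCardinality(1)]

model = scan_native_model([Person, ResearchGroup])
g = apply_semantics(map_structure(model), model)
print(serialize(g, "turtle"))
```

prints (abridged; the datatype and object properties come first):

```turtle
:researchGroups a owl:ObjectProperty ;
    rdfs:domain :Person ;
    rdfs:range :ResearchGroup .

:Person a owl:Class ;
    semantic:javaclass "__main__.Person" ;
    rdfs:subClassOf [ a owl:Restriction ;
            owl:cardinality "1"^^xsd:int ;
            owl:onProperty :dateofBirth ],
        [ a owl:Restriction ;
            owl:onProperty :firstname ;
            owl:someValuesFrom [ a owl:DataRange ;
                    owl:oneOf ( "http://cz.zcu.kiv/GivenNames"^^xsd:string ) ] ],
        [ a owl:Restriction ;
            owl:minCardinality "1"^^xsd:int ;
            owl:onProperty :researchGroups ] ;
    owl:equivalentClass <http://cz.zcu.kiv/TestedSubject> .
```

`Person` is equivalent to the external `TestedSubject` class and a subclass
of three anonymous restrictions: exactly one date of birth, at least one
research group, and a first name drawn from the `GivenNames` value set.

The same pipeline is available from the shell:

```bash
owlbind generate --fixture eeg --fixture-n 2 --seed 1 --syntax turtle
owlbind generate --model-doc model.yaml --syntax ntriples --out onto.nt
owlbind validate --model-doc model.yaml --instances records.json
owlbind syntaxes
```

Supported syntaxes: `rdfxml`, `rdfxml-abbrev`, `turtle`, `ntriples`, `n3`.
All are functionally equivalent — serializing and parsing back in any pair of
syntaxes yields isomorphic graphs — and emission is deterministic, so the
same model always produces the same document.

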