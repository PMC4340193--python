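classes:
- name: Experiment
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: startTime
    type: datetime
  - name: temperature
    type: decimal
  - name: person
    type: Person
  - name: scenario
    type: Scenario
  - name: hardware
    type: HardwareEquipment
  - name: data
    type: Data
- name: Person
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: firstname
    type: string
    annotations:
    - marker: SomeValuesFrom
      string_values:
      - http://cz.zcu.kiv/GivenNames
  - name: lastname
    type: string
    annotations:
    - marker: EquivalentProperty
      resource: http://www.kiv.zcu.cz/first_name
  - name: dateofBirth
    type: date
    annotations:
    - marker: Cardinality
      number: 1
  - name: researchGroups
    type: ResearchGroup
    collection: true
    annotations:
    - marker: MinCardinality
      number: 1
  - name: colleagues
    type: Person
    collection: true
    annotations:
    - marker: Symmetric
  - name: supervisor
    type: Person
    annotations:
    - marker: Inverse
      resource: http://cz.zcu.kiv/supervises
  - name: ancestors
    type: Person
    collection: true
    annotations:
    - marker: Transitive
  - name: experiments
    type: Experiment
    collection: true
    annotations:
    - marker: AllValuesFrom
      resource: http://cz.zcu.kiv/Experiment
  - name: phoneNumber
    type: string
    annotations:
    - marker: MaxCardinality
      number: 1
  - name: gender
    type: Gender
  - name: laterality
    type: string
  - name: education
    type: string
  annotations:
  - marker: EquivalentClass
    resource: http://cz.zcu.kiv/TestedSubject
  - marker: SameAs
    resource: http://cz.zcu.kiv/Subject
  - marker: DifferentFrom
    resource: http://cz.zcu.kiv/Experimenter
  - marker: AllDifferent
    resource: http://www.kiv.zcu.cz/#AllDifferent
- name: Gender
  package: cz.zcu.kiv
  enum:
  - MALE
  - FEMALE
- name: ResearchGroup
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: title
    type: string
- name: Scenario
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: title
    type: string
  - name: description
    type: string
- name: Data
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: filename
    type: string
  - name: samplingRate
    type: decimal
- name: Activity
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: stimulation
    type: string
  - name: instructions
    type: string
- name: Environment
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: weather
    type: string
  - name: roomTemperature
    type: decimal
  - name: daytime
    type: string
- name: HardwareEquipment
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: type
    type: string
  - name: producer
    type: string
  - name: serialNumber
    type: string
- name: SoftwareEquipment
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: name
    type: string
  - name: version
    type: string
- name: Electrode
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: electrodeType
    type: string
  - name: impedance
    type: decimal
  - name: location
    type: string
- name: DataDigitalization
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: filtration
    type: string
  - name: samplingFrequency
    type: decimal
- name: SignalAnalysis
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: preStimulusMs
    type: integer
  - name: postStimulusMs
    type: integer
  - name: epochCount
    type: integer
- name: DataPresentation
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: averagedWaves
    type: string
  - name: rawDataLink
    type: string
- name: SignalArtifact
  package: cz.zcu.kiv
  fields:
  - name: id
    type: integer
    id: true
  - name: compensationMethod
    type: string
  - name: rejectionCondition
    type: string
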