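# Miniature clinical-trial annotation schema.
# Covers the core template chain Publication -> ClinicalTrial -> Arm ->
# Intervention -> Medication and Outcome -> Endpoint, enough to exercise
# every scorer; the fuller configuration lives in ctro_schema.yaml.
categories:
  - {name: Drug, kind: individual}
  - {name: Bimatoprost, parent: Drug, kind: individual}
  - {name: Timolol, parent: Drug, kind: individual}
  - {name: Latanoprost, parent: Drug, kind: individual}
  - {name: Travoprost, parent: Drug, kind: individual}
  - {name: ConcentrationUnit, kind: individual}
  - {name: Percentage, parent: ConcentrationUnit, kind: individual}
  - {name: AggregationMethod, kind: individual}
  - {name: Mean, parent: AggregationMethod, kind: individual}
  - {name: DisorderOrSyndrome, kind: individual}
  - {name: Glaucoma, parent: DisorderOrSyndrome, kind: individual}
  - {name: AngleClosureGlaucoma, parent: Glaucoma, kind: individual}
  - {name: Country, kind: individual}
  - {name: Frequency, kind: literal}
  - {name: DoseValue, kind: literal}
  - {name: ChangeValue, kind: literal}
  - {name: TimePoint, kind: literal}
  - {name: EndPointDescription, kind: literal}
  - {name: Precondition, kind: literal}
  - {name: ConclusionComment, kind: literal}
  - {name: NumberPatientsArm, kind: literal}
  - {name: Author, kind: literal}
  - {name: Title, kind: literal}
  - {name: PMID, kind: literal}
  - {name: PublicationYear, kind: literal}
templates:
  - name: Publication
    slots:
      - {name: hasAuthor, filler_kind: entity, allowed_types: [Author]}
      - {name: hasTitle, filler_kind: entity, allowed_types: [Title], functional: true}
      - {name: hasPMID, filler_kind: entity, allowed_types: [PMID], functional: true}
      - {name: hasPublicationYear, filler_kind: entity, allowed_types: [PublicationYear], functional: true}
      - {name: describes, filler_kind: template, allowed_types: [ClinicalTrial], functional: true}
  - name: ClinicalTrial
    slots:
      - {name: hasArm, filler_kind: template, allowed_types: [Arm]}
      - {name: hasPopulation, filler_kind: template, allowed_types: [Population], functional: true}
      - {name: hasDiffBetweenGroups, filler_kind: template, allowed_types: [DiffBetweenGroups]}
      - {name: hasConclusionComment, filler_kind: entity, allowed_types: [ConclusionComment]}
      - {name: analysesHealthCondition, filler_kind: entity, allowed_types: [DisorderOrSyndrome]}
  - name: Population
    slots:
      - {name: hasPrecondition, filler_kind: entity, allowed_types: [Precondition]}
      - {name: hasCountry, filler_kind: entity, allowed_types: [Country]}
  - name: Arm
    slots:
      - {name: hasNumberPatientsArm, filler_kind: entity, allowed_types: [NumberPatientsArm], functional: true}
      - {name: hasIntervention, filler_kind: template, allowed_types: [Intervention]}
      - {name: hasOutcome, filler_kind: template, allowed_types: [Outcome]}
  - name: Intervention
    slots:
      - {name: hasFrequency, filler_kind: literal, functional: true}
      - {name: hasMedication, filler_kind: template, allowed_types: [Medication]}
  - name: Medication
    slots:
      - {name: hasDrug, filler_kind: entity, allowed_types: [Drug], functional: true}
      - {name: hasDoseValue, filler_kind: literal, functional: true}
      - {name: hasDoseUnit, filler_kind: entity, allowed_types: [ConcentrationUnit], functional: true}
  - name: Endpoint
    slots:
      - {name: hasEndoPointDescription, filler_kind: entity, allowed_types: [EndPointDescription], functional: true}
      - {name: hasAggregationMethod, filler_kind: entity, allowed_types: [AggregationMethod], functional: true}
  - name: Outcome
    slots:
      - {name: hasEndpoint, filler_kind: template, allowed_types: [Endpoint], functional: true}
      - {name: hasChangeValue, filler_kind: literal, functional: true}
      - {name: hasTimePoint, filler_kind: entity, allowed_types: [TimePoint]}
  - name: DiffBetweenGroups
    slots:
      - {name: hasOutcome1, filler_kind: template, allowed_types: [Outcome], functional: true}
      - {name: hasOutcome2, filler_kind: template, allowed_types: [Outcome], functional: true}
      - {name: hasPvalueDiff, filler_kind: literal, functional: true}
grouping: {}
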