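# CHQA-email annotation scheme: long consumer-health email requests.
# 17 named-entity categories, 33 question types, topic annotated as an
# entity attribute, nested entities allowed.
name: chqa-email

entity_categories:
  - ANATOMY
  - CELLULAR_ENTITY
  - DIAGNOSTIC_PROCEDURE
  - DRUG_SUPPLEMENT
  - FOOD
  - GENE_PROTEIN
  - GEOGRAPHIC_LOCATION
  - LIFESTYLE
  - MEASUREMENT
  - ORGANIZATION
  - PERSON_POPULATION
  - PROBLEM
  - PROCEDURE_DEVICE
  - PROFESSION
  - SUBSTANCE
  - OTHER
  - ORGANISM_FUNCTION

question_types:
  # general
  - COMPARISON
  - INFORMATION
  - OTHER_QUESTION
  # problem
  - CAUSE
  - COMPLICATION
  - DIAGNOSIS
  - EFFECT
  - FREQUENCY
  - INHERITANCE
  - LIFESTYLE_DIET
  - LOCATION
  - PERSON_ORGANIZATION
  - PREVENTION
  - PROGNOSIS
  - SUPPORT_GROUP
  - SUSCEPTIBILITY
  - SYMPTOM
  - TREATMENT
  # intervention
  - ACTION
  - ALTERNATIVE
  - CONTRAINDICATION
  - COST
  - DOSAGE
  - INDICATION
  - INGREDIENT
  - INTERACTION
  - LONG_TERM_EFFECT
  - OVERDOSE
  - SIDE_EFFECT
  - STORAGE_DISPOSAL
  - TAPERING
  - USAGE
  - DRUG_QUESTION

roles:
  - THEME
  - KEYWORD
  - EXCLUDE_KEYWORD

frame_attributes:
  - RESEARCH

# Allowed THEME entity categories per question type.  An empty list means
# any entity category may fill the THEME slot.
theme_restrictions:
  COMPARISON: []
  INFORMATION: []
  OTHER_QUESTION: []
  CAUSE: [PROBLEM]
  DIAGNOSIS: [PROBLEM]
  FREQUENCY: [PROBLEM]
  INHERITANCE: [PROBLEM]
  PREVENTION: [PROBLEM]
  SUSCEPTIBILITY: [PROBLEM]
  SYMPTOM: [PROBLEM]
  TREATMENT: [PROBLEM]
  COMPLICATION: [PROBLEM, PROCEDURE_DEVICE, LIFESTYLE, FOOD]
  EFFECT: [PROBLEM, PROCEDURE_DEVICE]
  LIFESTYLE_DIET: [PROBLEM, PROCEDURE_DEVICE]
  LOCATION: [PROBLEM, PROCEDURE_DEVICE]
  PROGNOSIS: [PROBLEM, PROCEDURE_DEVICE]
  PERSON_ORGANIZATION: [PROBLEM, PROCEDURE_DEVICE, DIAGNOSTIC_PROCEDURE]
  SUPPORT_GROUP: [PROBLEM, PROCEDURE_DEVICE, DIAGNOSTIC_PROCEDURE]
  ACTION: [DRUG_SUPPLEMENT, SUBSTANCE]
  DOSAGE: [DRUG_SUPPLEMENT, SUBSTANCE]
  DRUG_QUESTION: [DRUG_SUPPLEMENT, SUBSTANCE]
  INGREDIENT: [DRUG_SUPPLEMENT, SUBSTANCE]
  OVERDOSE: [DRUG_SUPPLEMENT, SUBSTANCE]
  ALTERNATIVE: [DRUG_SUPPLEMENT, SUBSTANCE, PROCEDURE_DEVICE, DIAGNOSTIC_PROCEDURE]
  COST: [DRUG_SUPPLEMENT, SUBSTANCE, PROCEDURE_DEVICE, DIAGNOSTIC_PROCEDURE]
  INDICATION: [DRUG_SUPPLEMENT, SUBSTANCE, PROCEDURE_DEVICE, DIAGNOSTIC_PROCEDURE]
  LONG_TERM_EFFECT: [DRUG_SUPPLEMENT, SUBSTANCE, PROCEDURE_DEVICE, DIAGNOSTIC_PROCEDURE]
  SIDE_EFFECT: [DRUG_SUPPLEMENT, SUBSTANCE, PROCEDURE_DEVICE, DIAGNOSTIC_PROCEDURE]
  USAGE: [DRUG_SUPPLEMENT, SUBSTANCE, PROCEDURE_DEVICE, DIAGNOSTIC_PROCEDURE]
  CONTRAINDICATION: [DRUG_SUPPLEMENT, SUBSTANCE, PROCEDURE_DEVICE]
  STORAGE_DISPOSAL: [DRUG_SUPPLEMENT, SUBSTANCE, PROCEDURE_DEVICE]
  TAPERING: [DRUG_SUPPLEMENT, SUBSTANCE, PROCEDURE_DEVICE]
  INTERACTION: [DRUG_SUPPLEMENT, SUBSTANCE]

# THEME cardinality per question type as [min, max]; max null = unbounded.
# Types not listed use the default of exactly one THEME.
theme_cardinality:
  COMPARISON: [2, null]
  INTERACTION: [2, null]
  EFFECT: [1, null]

topic_required: true
nested_entities_allowed: true
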