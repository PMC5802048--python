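# CHQA-web annotation scheme: short natural-language questions harvested
# from search query logs.  18 named-entity categories (RESEARCH_CUE added),
# 26 question types after consolidation, THEME type restrictions lifted,
# no explicit topic annotation, no nested entities.
name: chqa-web

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
  - RESEARCH_CUE

question_types:
  # general
  - COMPARISON
  - INFORMATION
  - OTHER_QUESTION
  - TIME
  # problem
  - ASSOCIATION        # generalization/rename of EFFECT
  - CAUSE
  - COMPLICATION       # absorbs LONG_TERM_EFFECT, OVERDOSE, SIDE_EFFECT
  - DIAGNOSE_ME
  - DIAGNOSIS
  - LIFESTYLE_DIET
  - LOCATION
  - PERSON_ORGANIZATION  # absorbs SUPPORT_GROUP
  - PREVENTION
  - PROGNOSIS
  - SUSCEPTIBILITY     # absorbs FREQUENCY, INHERITANCE
  - SYMPTOM
  - TREATMENT
  # intervention
  - ACTION
  - ALTERNATIVE
  - CONTRAINDICATION
  - COST
  - INDICATION
  - INGREDIENT
  - INTERACTION
  - USAGE              # absorbs DOSAGE, STORAGE_DISPOSAL, TAPERING
  - DRUG_QUESTION

roles:
  - THEME
  - AGENT
  - LOCATIVE
  - PATIENT
  - PURPOSE
  - RESTRICTOR
  - TEMPORAL
  - RESEARCH

frame_attributes: []

# THEME type restrictions were lifted for this part of the corpus; every
# type maps to the unrestricted (empty) set.
theme_restrictions: {}

theme_cardinality:
  COMPARISON: [2, null]
  INTERACTION: [2, null]
  ASSOCIATION: [1, null]
  DIAGNOSE_ME: [1, null]
  TIME: [1, 1]

topic_required: false
nested_entities_allowed: false
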