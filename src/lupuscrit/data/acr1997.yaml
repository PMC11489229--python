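# ACR-1997 revised classification criteria for SLE: 11 items, classify
# when at least 4 are present.  Item predicates are expressed over the
# registry vocabulary; composite items (renal, hematologic, immunologic)
# are ORs of their component features.
name: ACR-1997
rule_kind: count_threshold
threshold: 4
threshold_is_strict: false
items:
  - {item_id: malar_rash,       predicate: malar_rash,       category: clinical}
  - {item_id: discoid_rash,     predicate: scle_dle,         category: clinical}
  - {item_id: photosensitivity, predicate: photosensitivity, category: clinical}
  - {item_id: oral_ulcers,      predicate: mucosal_ulcers,   category: clinical}
  - {item_id: arthritis,        predicate: arthritis,        category: clinical}
  - {item_id: serositis,        predicate: serositis,        category: clinical}
  - {item_id: renal_disorder,   predicate: proteinuria or biopsy_proven_nephritis, category: clinical}
  - {item_id: neurologic_disorder, predicate: neurological_disorder, category: clinical}
  - {item_id: hematologic_disorder, predicate: leucopenia or thrombocytopenia_aiha or anemia, category: clinical}
  - {item_id: immunologic_disorder, predicate: immunological_disorder or anti_dsdna or anti_sm or antiphospholipid, category: immunologic}
  - {item_id: ana,              predicate: ana,              category: immunologic}
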