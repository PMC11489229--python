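# SLICC-2012 classification criteria for SLE: 17 items (11 clinical,
# 6 immunologic).  Classify when >= 4 items are satisfied including at
# least one clinical and one immunologic item, OR by the standalone
# organ-dominant rule: biopsy-proven lupus nephritis with ANA or
# anti-dsDNA.
#
# Registry mapping notes: the registry's merged immunological-disorder
# flag backs the anti-dsDNA item (its most common component) and is not
# repeated under anti-Sm/antiphospholipid, which have their own features,
# so a single merged flag can satisfy at most one antibody item.
name: SLICC-2012
rule_kind: count_threshold
threshold: 4
threshold_is_strict: false
min_clinical: 1
min_immunologic: 1
standalone:
  - biopsy_proven_nephritis and (ana or anti_dsdna)
items:
  - {item_id: acute_cutaneous_lupus,   predicate: malar_rash,            category: clinical}
  - {item_id: chronic_cutaneous_lupus, predicate: scle_dle,              category: clinical}
  - {item_id: oral_nasal_ulcers,       predicate: mucosal_ulcers,        category: clinical}
  - {item_id: nonscarring_alopecia,    predicate: alopecia,              category: clinical}
  - {item_id: synovitis,               predicate: arthritis,             category: clinical}
  - {item_id: serositis,               predicate: serositis,             category: clinical}
  - {item_id: renal,                   predicate: proteinuria or biopsy_proven_nephritis, category: clinical}
  - {item_id: neurologic,              predicate: neurological_disorder, category: clinical}
  - {item_id: hemolytic_anemia,        predicate: anemia,                category: clinical}
  - {item_id: leukopenia_lymphopenia,  predicate: leucopenia,            category: clinical}
  - {item_id: thrombocytopenia,        predicate: thrombocytopenia_aiha, category: clinical}
  - {item_id: ana,                     predicate: ana,                   category: immunologic}
  - {item_id: anti_dsdna,              predicate: anti_dsdna or immunological_disorder, category: immunologic}
  - {item_id: anti_sm,                 predicate: anti_sm,               category: immunologic}
  - {item_id: antiphospholipid,        predicate: antiphospholipid,      category: immunologic}
  - {item_id: low_complement,          predicate: low_c3_c4,             category: immunologic}
  - {item_id: direct_coombs,           predicate: direct_coombs,         category: immunologic}
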