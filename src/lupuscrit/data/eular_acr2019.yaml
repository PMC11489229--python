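# EULAR/ACR-2019 classification criteria for SLE: ANA entry criterion,
# then additively weighted criteria grouped in domains; within each
# domain only the highest-weighted satisfied item counts.  Classify at a
# total of >= 10 points.
#
# Registry mapping notes: the neuropsychiatric domain (delirium 2 /
# psychosis 3 / seizure 5) is collapsed onto the registry's single
# neurological-disorder flag at the domain maximum of 5; the serosal
# domain uses the effusion weight 5 for the merged serositis flag; the
# merged low-C3-and-C4 flag takes the both-low weight 4; the merged
# immunological-disorder flag backs the SLE-specific antibody domain
# (anti-dsDNA / anti-Sm, weight 6).  The "not better explained by another
# disease" attribution clause is not computable from a binary feature
# table and is omitted.
name: EULAR/ACR-2019
rule_kind: domain_weighted_threshold
threshold: 10
threshold_is_strict: false
entry: ana
items:
  - {item_id: fever,                 predicate: fever,                 weight: 2,  domain: constitutional}
  - {item_id: leukopenia,            predicate: leucopenia,            weight: 3,  domain: hematologic}
  - {item_id: thrombocytopenia,      predicate: thrombocytopenia_aiha, weight: 4,  domain: hematologic}
  - {item_id: autoimmune_hemolysis,  predicate: anemia,                weight: 4,  domain: hematologic}
  - {item_id: neuropsychiatric,      predicate: neurological_disorder, weight: 5,  domain: neuropsychiatric}
  - {item_id: nonscarring_alopecia,  predicate: alopecia,              weight: 2,  domain: mucocutaneous}
  - {item_id: oral_ulcers,           predicate: mucosal_ulcers,        weight: 2,  domain: mucocutaneous}
  - {item_id: subacute_discoid_lupus, predicate: scle_dle,             weight: 4,  domain: mucocutaneous}
  - {item_id: acute_cutaneous_lupus, predicate: malar_rash,            weight: 6,  domain: mucocutaneous}
  - {item_id: serositis,             predicate: serositis,             weight: 5,  domain: serosal}
  - {item_id: joint_involvement,     predicate: arthritis,             weight: 6,  domain: musculoskeletal}
  - {item_id: proteinuria,           predicate: proteinuria,           weight: 4,  domain: renal}
  - {item_id: biopsy_nephritis,      predicate: biopsy_proven_nephritis, weight: 10, domain: renal}
  - {item_id: antiphospholipid,      predicate: antiphospholipid,      weight: 2,  domain: antiphospholipid}
  - {item_id: low_c3_and_c4,         predicate: low_c3_c4,             weight: 4,  domain: complement}
  - {item_id: sle_specific_antibody, predicate: anti_dsdna or anti_sm or immunological_disorder, weight: 6, domain: specific_antibodies}
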