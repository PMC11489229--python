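# SLE Risk Probability Index (SLERPI), simplified weighted score.
#
# 14 items: 13 positively weighted lupus features plus interstitial lung
# disease at -1 (the single feature counting against lupus).  Weights are
# calibrated to the published anchors of the simplified score: positive
# weights sum to 30.5, thrombocytopenia/AIHA carries the largest single
# weight (4.5), and classification requires a score strictly greater
# than 7.
#
# The probability transform maps the score to a lupus probability via the
# inverse logit centred on the binary threshold, so probability > 50%
# coincides exactly with score > 7; categories use the ordinal bins
# unlikely [0,15) / possible [15,44) / likely [44,87) / definite [87,100].
name: SLERPI
rule_kind: weighted_sum_threshold
threshold: 7
threshold_is_strict: true
category_cutpoints: [15, 44, 87]
items:
  - {item_id: malar_rash,             predicate: malar_rash,             weight: 4.0,  category: clinical}
  - {item_id: scle_dle,               predicate: scle_dle,               weight: 2.5,  category: clinical}
  - {item_id: alopecia,               predicate: alopecia,               weight: 1.0,  category: clinical}
  - {item_id: mucosal_ulcers,         predicate: mucosal_ulcers,         weight: 1.0,  category: clinical}
  - {item_id: arthritis,              predicate: arthritis,              weight: 1.5,  category: clinical}
  - {item_id: serositis,              predicate: serositis,              weight: 2.0,  category: clinical}
  - {item_id: neurological_disorder,  predicate: neurological_disorder,  weight: 3.0,  category: clinical}
  - {item_id: leucopenia,             predicate: leucopenia,             weight: 1.5,  category: clinical}
  - {item_id: thrombocytopenia_aiha,  predicate: thrombocytopenia_aiha,  weight: 4.5,  category: clinical}
  - {item_id: proteinuria,            predicate: proteinuria,            weight: 2.5,  category: clinical}
  - {item_id: ana,                    predicate: ana,                    weight: 3.0,  category: immunologic}
  - {item_id: low_c3_c4,              predicate: low_c3_c4,              weight: 2.0,  category: immunologic}
  - {item_id: immunological_disorder, predicate: immunological_disorder, weight: 2.0,  category: immunologic}
  - {item_id: ild,                    predicate: ild,                    weight: -1.0, category: clinical}
probability_transform:
  intercept: -7.0
  coefficients:
    malar_rash: 4.0
    scle_dle: 2.5
    alopecia: 1.0
    mucosal_ulcers: 1.0
    arthritis: 1.5
    serositis: 2.0
    neurological_disorder: 3.0
    leucopenia: 1.5
    thrombocytopenia_aiha: 4.5
    proteinuria: 2.5
    ana: 3.0
    low_c3_c4: 2.0
    immunological_disorder: 2.0
    ild: -1.0
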