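# lupuscrit

Rule-based classification criteria engines for systemic lupus
erythematosus (SLE), with a synthetic case-control cohort generator and a
diagnostic-performance evaluation layer.

## The problem

Classifying SLE against other autoimmune diseases is done with rule
systems over binary clinical and serological findings. Four systems are
in routine use, and validation studies compare them on case-control
cohorts:

- **SLERPI** (SLE Risk Probability Index): 14 weighted features; the
  simplified score classifies SLE when

  *S* = Σᵢ wᵢ·xᵢ **> 7**, with max Σ(wᵢ > 0) = **30.5**,

  where each xᵢ ∈ {0,1} marks a feature (malar/maculopapular rash,
  SCLE/DLE, alopecia, mucosal ulcers, arthritis, serositis, neurological
  disorder, leucopenia, thrombocytopenia/AIHA, proteinuria, ANA, low C3
  and C4, immunological disorder) and interstitial lung disease is the
  single negative item (w = −1). A logistic transform maps the score to
  a probability percentage, binned into the ordinal categories
  *unlikely* [0, 15), *possible* [15, 44), *likely* [44, 87) and
  *definite* [87, 100].
- **ACR-1997**: ≥ 4 of 11 items.
- **SLICC-2012**: ≥ 4 of 17 items with ≥ 1 clinical and ≥ 1 immunologic
  item, or standalone biopsy-proven nephritis with ANA or anti-dsDNA.
- **EULAR/ACR-2019**: ANA entry criterion, then ≥ 10 points of weighted
  criteria where only the highest-weighted satisfied item per domain
  counts.

`lupuscrit` implements all four as declarative, validated YAML
definitions evaluated by three generic engines (weighted sum, count
threshold, domain-weighted threshold), plus:

- a **synthetic cohort generator** reproducing the marginal feature
  structure of a 435-case / 430-control validation population (per-group
  Bernoulli prevalences, 18.4% overt polyautoimmunity in both groups, a
  six-disease control mix, subphenotype flags), with an opt-in
  Gaussian-copula scheme for correlated features;
- an **evaluation layer**: confusion matrices, sensitivity/specificity/
  accuracy with exact Clopper–Pearson intervals, ROC/AUC (midrank ties,
  so AUC = U/(n₁n₂)), subgroup analyses, and an integer-count
  reconstruction that audits printed percentage tables;
- **association statistics**: OLS feature attribution for the SLERPI
  outcome, Mann–Whitney U, chi-square, and Lilliefors-corrected KS
  normality screening.

## Worked example

```python
from lupuscrit import PatientRecord, Group, load_all_bundled, score_record

patient = PatientRecord(
    id="pt-001", group=Group.case,
    features={"malar_rash": 1, "ana": 1,
              "immunological_disorder": 1, "low_c3_c4": 1},
)
for criteria in load_all_bundled():
    r = score_record(patient, criteria)
    print(criteria.name, r.score, r.classified, r.probability_pct, r.category)
```

prints

```
ACR-1997 3.0 0 None None
SLICC-2012 4.0 1 None None
EULAR/ACR-2019 16.0 1 None None
SLERPI 11.0 1 98.20137900379083 Category.definite
```

The patient misses ACR-1997 (3 of 11 items, below the threshold of 4)
but satisfies SLICC-2012 (4 items, with clinical and immunologic
representation), EULAR/ACR-2019 (ANA entry, then 6 + 6 + 4 = 16 ≥ 10
points from the mucocutaneous, antibody and complement domains) and
SLERPI (4 + 3 + 2 + 2 = 11 > 7; probability 98.2%, category *definite*).

A full synthetic validation run:

```bash
lupuscrit run --seed 1 --out-dir out/
```

writes `out/report.json` with, per criteria set, overall and stratified
(by polyautoimmunity and by the neuropsychiatric / nephritis /
hematological subphenotypes) performance blocks, the ROC AUC with a
DeLong interval, the SLERPI ordinal category distribution, and the
pooled OLS regression of the SLERPI probability on the 14 features. At
seed 1 the synthetic cohort gives SLERPI sensitivity 95.2%, specificity
96.0%, AUC 0.993, with 87.6% of cases in the *definite* category and
immunological disorder and malar rash carrying the largest regression
coefficients — the qualitative profile expected of a well-separated
case-control population with these marginals.

Other entry points: `lupuscrit generate` (cohort CSV),
`lupuscrit score`, `lupuscrit evaluate`, `lupuscrit associate`.

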