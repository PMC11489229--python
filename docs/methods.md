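# Methods

## Criteria engines

All four criteria sets are data, not code: YAML documents validated at
load time (pydantic; the accepted shape is also described by
`src/lupuscrit/data/criteria.schema.json`). Item predicates are boolean
expressions (`and` / `or` / `not`, parentheses) over a declared
vocabulary of binary features; an absent feature evaluates to 0, the
usual retrospective-registry convention for unobserved findings. Three
engines interpret the definitions:

- **weighted_sum_threshold** — score = Σ wᵢ·xᵢ; SLERPI uses a *strict*
  threshold (score > 7), so a score of exactly 7 does not classify.
- **count_threshold** — score = number of satisfied items; optional
  minimum counts of clinical and immunologic items (SLICC-2012 requires
  one of each) and standalone rules that classify on their own (the
  SLICC organ-dominant rule: biopsy-proven nephritis with ANA or
  anti-dsDNA).
- **domain_weighted_threshold** — an entry predicate gates everything
  (EULAR/ACR-2019: ANA; when it fails the result is flagged
  `entry_failed` and cannot classify); otherwise each domain contributes
  the maximum weight among its satisfied items and the total is compared
  non-strictly to the threshold (10).

### The bundled SLERPI definition

The simplified SLERPI score is published as a 14-item weighted rule with
structural anchors: positive weights summing to 30.5, the merged
thrombocytopenia/AIHA item carrying the largest single weight (4.5),
interstitial lung disease as the sole negative item (−1), and the strict
threshold at 7. The per-item weights bundled here are calibrated to
those anchors; they reproduce every published structural property the
package tests, but users validating against an external SLERPI
implementation should diff `src/lupuscrit/data/slerpi.yaml` against
their source and override the file if their transcription differs. All
bundled anchors are enforced at load time — a SLERPI definition whose
positive weights do not sum to 30.5 is rejected.

The probability transform is the package's own choice: probability =
100·σ(score − 7), the inverse logit centred on the binary threshold, so
that probability > 50% coincides exactly with the simplified rule and
the ROC operating point at 50% equals the score cutoff. Ordinal
categories bin the probability as unlikely [0, 15), possible [15, 44),
likely [44, 87), definite [87, 100]; the published integer ranges
(0–14, 15–43, …) leave fractional gaps, so the bins are implemented
half-open to make the mapping total. The transform is a configuration
field, not a constant — a definition may omit it (then only the score
and binary rule are produced) or replace it with fitted logistic
coefficients.

### Comparator transcription onto a merged-feature registry

The registry vocabulary records some findings merged (one
immunological-disorder flag covering the anti-dsDNA/anti-Sm/
antiphospholipid axis; one thrombocytopenia/AIHA flag; one low-C3-and-C4
flag; one neurological-disorder flag). Mapping decisions, all recorded
in the YAML files:

- the merged immunological-disorder flag backs exactly one antibody
  item per criteria set (SLICC anti-dsDNA; the EULAR SLE-specific
  antibody domain), never several at once, so a single merged flag
  cannot inflate item counts;
- EULAR's neuropsychiatric domain (2/3/5) collapses to one item at the
  domain maximum 5, its serosal domain to the effusion weight 5, and
  the merged complement flag takes the both-low weight 4;
- the EULAR attribution clause ("not better explained by another
  disease") is not computable from a binary feature table and is
  omitted;
- items with no registry counterpart (fever, photosensitivity,
  anti-Sm, antiphospholipid, direct Coombs, hemolytic anemia, biopsy
  findings) are auxiliary vocabulary features that default to
  prevalence 0 in the generator and can be switched on per run.

## Synthetic cohort generator

The generator emulates the printed summary structure of a 435-case /
430-control validation population: per-group Bernoulli prevalences for
the 14 SLERPI features (e.g. ANA 93.3% in cases vs 58.8% in controls;
ILD 0% in cases), overt polyautoimmunity at 18.4% in both groups
independent of features, a fixed control index-disease mix (RA 253,
SS 56, AITD 43, MS 47, SSc 30, APS 1; shuffled assignment, exact
counts), and demographics (sex frequencies; ages log-normal matched to
the printed median and IQR — cosmetic only, excluded from every
quantitative check).

Features are drawn **independently** by default because published
tables constrain only the marginals. Dependence is opt-in via a
Gaussian copula: latent z ~ N(0, R) thresholded at Φ⁻¹(pⱼ) per feature,
with R validated as symmetric, unit-diagonal and positive semidefinite
(eigenvalue factorization clipped at zero, so a PSD boundary matrix is
handled without failure). With R = I the copula reduces to the
independent generator in distribution. Degenerate prevalences 0 and 1
produce constant columns (Φ⁻¹ gives ∓∞ thresholds; handled explicitly).

Subphenotype flags are **feature-coupled** by default — neuropsychiatric
⇔ neurological disorder, nephritis ⇔ proteinuria, hematological ⇔
(leucopenia ∨ thrombocytopenia/AIHA ∨ anemia) — mirroring the
near-identical printed flag and feature counts (88/88, 125/124,
173/175); an `independent` mode draws the flags at the printed
frequencies unlinked to features. Under independence the hematological
OR yields ~46% of cases versus the printed 40%, a known consequence of
ignoring the real data's feature overlap; no quantitative check depends
on it.

Randomness: a single seed feeds `numpy.random.SeedSequence`, which
spawns one substream per stage (features, polyautoimmunity, control
mix, subphenotypes, ages, sex), making every output byte-reproducible
and insensitive to stage reordering.

What passing on this generator does and does not show: it validates the
engines, the evaluation arithmetic and the qualitative performance
profile (high sensitivity and specificity, AUC ≫ 0.9), but marginals do
not pin the joint feature distribution, so synthetic operating
characteristics are not expected to equal published ones to the decimal.

## Evaluation layer

- Sensitivity tp/(tp+fn), specificity tn/(fp+tn), accuracy
  (tp+tn)/total, each with the exact **Clopper–Pearson** interval (beta
  quantiles; closed at 0 and 1). Wilson intervals are available behind a
  flag. Printed-table comparisons round half away from zero to one
  decimal (`round_half_away`), the convention of clinical tables —
  Python's banker's rounding differs at ties.
- Subgroup analyses restrict the **case** set only (polyautoimmunity
  strata, subphenotypes); the full control group is always retained, so
  specificity is identical across subgroups by construction.
- ROC curves are built over all distinct thresholds of the continuous
  SLERPI probability when available (raw score otherwise); trapezoidal
  AUC with midrank ties, hence AUC ≡ U/(n₁n₂). An optional DeLong
  variance interval accompanies the AUC.
- `reconstruct_count(rate, n)` inverts one-decimal percentage rounding
  to the unique implied integer numerator, erroring on both
  inconsistency (no integer rounds to the rate) and ambiguity (several
  do). This powers the internal-consistency audit of published
  performance tables (`lupuscrit.audit`): reconstruct TP and TN from a
  row's sensitivity/specificity and group sizes, re-derive the accuracy,
  compare to one decimal. Ten of the eleven bundled reported rows pass;
  the without-polyautoimmunity SLERPI row is inconsistent as printed
  (implied 336/355 and 403/430 give 94.1 vs the printed 94.2) and is
  carried with `consistent=False` so the audit surfaces rather than
  silences it.

## Association statistics

- **OLS** (statsmodels) of the SLERPI probability percentage — the
  scale on which group medians like 99.98 vs 2.12 are reported; the raw
  score is a switch — on the 14 binary features, pooled over cases and
  controls. Structurally constant columns (a feature absent from the
  whole sample) are dropped with a warning and listed in the result;
  remaining rank deficiency is an error naming the columns. On default
  synthetic cohorts the largest coefficients are immunological disorder
  and malar rash, echoing the expected attribution ordering.
- **Mann–Whitney U** with midrank ties: exact null distribution for
  small untied samples (min n < 8), tie-corrected continuity-corrected
  normal approximation otherwise.
- **Chi-square** with Yates correction for 2×2 (flag to disable).
- **KS normality** against a normal with estimated mean/SD: with
  estimated parameters the plain KS p-value is anticonservative in
  form and wildly conservative in practice, so the **Lilliefors**
  correction is the default and both p-values are reported. Constant
  samples are an error; n < 50 warns.
- p-values below 10⁻⁴ are formatted as "<0.0001" in reports. No
  multiple-testing adjustment is applied (none is part of the emulated
  analysis); reports state this.

## Pipeline and problem sizes

`run_pipeline` is deterministic given config + seed and writes a
sorted-keys JSON report (provenance: package version, seed, config
hash). The test suite and `scripts/acceptance.py` use the study-sized
cohort (865 subjects) for end-to-end checks, 50,000 per group for
generator marginal calibration, 1,000–10,000 replicates for the
simulation-based calibration checks (interval coverage, chi-square
type-I error, Lilliefors size), and exhaustive enumeration for the
small oracles (domain-max subsets, permutation null, count
reconstruction) — sizes chosen so every stochastic check is decisively
powered while the whole suite stays lightweight.

## Known limitations

- Feature independence is the default generator regime; real cohorts
  have correlated manifestations, and subphenotype overlap shifts ORs
  of features accordingly.
- The comparator definitions operate on merged registry flags, so they
  are coarser than the full published item lists (e.g. no lymphopenia
  distinct from leucopenia, no renal biopsy classes).
- The SLERPI per-item weights reproduce the published structural
  anchors but are not a verbatim transcription of the original model;
  swap in `slerpi.yaml` from a primary source for exact-weight work.
- Ordinal category percentages and the binary rule can disagree for
  borderline patients under a replaced probability transform whose 50%
  point is not at the score threshold; the bundled transform avoids
  this by construction.
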