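# Methods

This note documents the models, conventions and design decisions behind
`edscores`, in the package's own words. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Score calculators

RAPS, REMS, MEWS and MEDS are lookup-table scores: each input variable
falls into a point band and the total is the sum of the per-variable
points. The calculators return a `ScoreBreakdown` carrying the total and
the full per-variable attribution, so a clinician (or a test) can see
exactly where points came from. Attainable ranges are RAPS 0–16,
REMS 0–26, MEWS 0–14, MEDS 0–27; the maxima are the column sums of the
band tables and are attained by the extreme profiles exercised in the
tests.

Conventions, where the published tables are silent or ambiguous:

- **Rounding.** The band tables are written over integer values
  (temperature over 0.1 °C). Real-valued inputs are rounded *half-up* to
  that resolution before lookup, via decimal (not binary-float)
  arithmetic, so 120.5/min → 121/min and 38.45 °C → 38.5 °C. Threshold
  criteria that are not band tables (the MEDS tachypnea/hypoxia rule
  RR > 20 or SpO₂ < 90) compare the measured value directly, strict
  inequalities as written.
- **MEWS band gaps.** The published MEWS table leaves systolic BP exactly
  70 mmHg (between "<70" and "71–80") and heart rate exactly 40/min
  (between "<40" and "41–50") unassigned. Both are scored in the adjacent
  *higher-acuity* band (+3 and +2): a conservative triage convention,
  pinned by boundary tests. The MEWS temperature row has no +1 or +3
  band; that is treated as a fact of the score, not an omission to
  repair.
- **AVPU from GCS.** When no explicit AVPU assessment is recorded, it is
  derived by the conventional correspondence 14–15 → Alert,
  9–13 → Voice, 4–8 → Pain, 3 → Unresponsive. An explicit AVPU always
  takes precedence.
- **Altered mental status (MEDS).** Taken from the chart-abstraction
  boolean when present; when absent, GCS ≤ 13 is the proxy. Septic shock
  is likewise consumed as a boolean flag — the package does not re-derive
  it from hemodynamics, because the clinical definition (consensus
  criteria with fluid-refractory hypotension) is not computable from a
  single triage snapshot.
- **Missing inputs.** By default a missing required input raises an error
  naming the field; there is no silent imputation. An opt-in
  `impute_normal` mode substitutes the midpoint of the zero-point band
  (e.g. pulse 90, MAP 90, RR 18, SpO₂ 95, SBP 150, T 36.7, GCS 15) and
  logs every substitution.

## Synthetic cohort generator

The motivating 114-patient multicenter splenic-abscess cohort is not
public at patient level; only arm-wise summaries are published
(median/IQR for continuous variables, frequencies for categorical ones,
for 100 survivors and 14 non-survivors). The generator turns those
summaries into a sampling model:

- **Continuous variables** (age, pulse rate, respiratory rate, MAP,
  temperature, platelets, leukocytes) are log-normal. Log-normals have
  positive support and the right skew typical of vitals and counts, and
  two parameters are exactly identifiable from a median and an IQR:
  μ = ln(median), and σ is the least-squares solution of the two
  log-quantile equations, σ = ln(q3/q1)/(2·z₀.₇₅). A log-symmetric IQR
  is reproduced exactly; otherwise the reported residual quantifies the
  asymmetry the two-parameter family cannot express. Samples are
  truncated to physiological bounds (e.g. pulse 20–250/min, temperature
  30–43 °C, age ≥ 18) *symmetrically in probability*: whatever tail mass
  the tighter bound removes is also removed from the other tail, so the
  target median survives truncation exactly. One published summary is
  degenerate — survivor respiratory rate 20 (IQR 19–20), median equal to
  the upper quartile — and cannot be represented by any continuous
  two-parameter fit; the default spec widens that q3 to 20.5, half the
  printed reporting resolution.
- **Categorical variables and flags** are count-calibrated: each
  category's count in an arm is fixed by largest-remainder rounding of
  n·p and the labels are randomly permuted across patients. A generated
  arm is thus a resample of the observed margins and reproduces the
  published frequencies essentially exactly at every seed, which is what
  "matching the published group frequencies" should mean for a
  calibration target. The published non-survivor septic-shock percentage
  is printed as 42.84% although the printed count is 6/14 = 42.86%; the
  generator uses the count.
- **GCS** is sampled in two stages: the published band (≤8 / 9–11 / ≥12),
  then an integer within the band — uniform within the two low bands,
  and weighted {12: 0.05, 13: 0.05, 14: 0.10, 15: 0.80} within ≥12,
  since most ward-admitted patients are fully alert.
- **Unreported inputs.** SpO₂ and systolic BP are not summarized in the
  source; defaults are SpO₂ ~ normal(97, 2) in survivors / (93, 4) in
  non-survivors clipped to [50, 100], and SBP = MAP + (2/3)·40 mmHg
  (fixed pulse pressure 40 mmHg). The four MEDS-only flags without
  published frequencies (nursing-home residency, lower respiratory
  infection, bands > 5%, mask oxygen) default to (0.05, 0.10, 0.15,
  0.05) in survivors and double in non-survivors. All of these are
  explicitly synthetic conventions, overridable in the spec, and never
  presented as published facts.
- **Independence.** Variables are independent within an arm. The source
  reports no correlation structure, so independence is the honest
  default — and a real limitation: in real patients shock, tachycardia,
  thrombocytopenia and depressed GCS co-occur, which concentrates
  acuity in fewer patients and typically *raises* multi-input score
  discrimination. Passing tests on synthetic cohorts therefore
  demonstrate that the machinery is correct and that effect directions
  are right, not that real-cohort AUROC values are reproduced. The
  published real-cohort AUROCs (MEDS 0.92, MEWS 0.76, RAPS 0.68,
  REMS 0.67) are unattainable without patient-level data; on large
  synthetic cohorts the package checks direction and ordering instead
  (all AUROCs > 0.5, higher predicted death probability in
  non-survivors, MEDS ranked first — its inputs carry the strongest
  published between-arm contrasts: septic shock 4% vs 42.9%, platelets,
  GCS, respiratory rate, age > 65).

Generation is deterministic given the spec seed, and the CSV writer is
byte-stable, so a (seed, spec) pair is a complete provenance record.

## Evaluation statistics

All statistics in the evaluation path are implemented in this package;
scipy, statsmodels and sklearn appear only as independent cross-checks
in the test suite.

- **Mann-Whitney U** (two-sided). The statistic is U of the first
  sample (tied pairs count one half, via midranks). Exact permutation
  p-values are computed whenever C(n₁+n₂, n₁) ≤ 10⁶ — by a rank-sum
  counting recursion without ties, by full enumeration of combinations
  with ties; the two-sided p is the permutation mass at least as far
  from n₁n₂/2 as observed. Otherwise the normal approximation is used,
  with midrank tie correction in the variance and a 0.5 continuity
  correction. A forced `exact` that is infeasible falls back with a
  logged note.
- **Fisher's exact test** (2×2, two-sided) sums hypergeometric
  probabilities of all tables no more probable than the observed one
  (relative tolerance 1+10⁻⁷ at ties, the common convention). Log-gamma
  arithmetic keeps it stable for large margins.
- **Logistic regression.** Univariate maximum likelihood by
  Newton/IRLS, initialized at (log-odds of the base rate, 0), converged
  when the gradient max-norm < 10⁻⁸, capped at 50 iterations. Complete
  separation is detected up front and reported with its direction;
  standard errors come from the inverse observed information. The
  probability of death is exactly p = 1/(1+exp(−(β₀+β₁·score))).
- **ROC/AUROC.** The curve runs over all distinct observed thresholds
  (ties grouped) under the convention *predicted positive iff
  score ≥ threshold*, from (0,0) to (1,1); AUROC is the trapezoidal
  area, which equals U/(n₊·n₋) with ties counted half — an identity the
  tests verify against the Mann-Whitney implementation on random data.
- **Optimal cutoff.** The published analyses report an "optimal cutoff"
  without naming the rule; this package uses Youden's J =
  sensitivity + specificity − 1, the default in ROC practice, with ties
  broken toward higher specificity and then toward the higher
  threshold. This is a package decision, not a published fact.
- **Test characteristics.** Sensitivity, specificity, PPV, NPV and
  accuracy are derived from integer confusion counts; empty denominators
  yield NaN rather than a silent 0. Percentages are reported to two
  decimals, matching clinical reporting style.
- **Univariate cohort comparisons.** Continuous variables use
  Mann-Whitney U; binary variables use Fisher's exact test. Multi-level
  categoricals (etiology, treatment, GCS bands, abscess multiplicity)
  are reported with per-level one-vs-rest 2×2 Fisher tests, since the
  exact test implemented here is 2×2; a 2×k network-algorithm exact test
  is out of scope.

## Problem sizes

The test suite and acceptance script choose sizes that make the checks
sharp but quick: calibration is asserted at 10⁴ patients per arm
(median sampling error ≈ 1%, well inside the 3% tolerance), ROC/ordering
checks at 50× the published composition (5 700 patients), and IRLS
recovery at 200 replicates of n = 5 000 (acceptance script: 50
replicates). The full suite runs in well under a minute on one CPU.

## Known limitations

- Independence across variables within an arm (above) is the dominant
  simplification; correlated-vitals (copula) generation is a non-goal.
- The exact Mann-Whitney enumeration with ties is combinatorial and is
  therefore gated by the same C(n, k) ≤ 10⁶ feasibility bound as the
  tie-free recursion.
- The logistic model is univariate by design (one score at a time), as
  in the source analyses; multivariable models, AUROC confidence
  intervals and curve-comparison tests are out of scope.
- Scores are computed from a single triage snapshot; no longitudinal
  track-and-trigger behaviour is modelled.
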