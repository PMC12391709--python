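# Methods

## The surveillance model

The pipeline models GTT-style active surveillance as four stages over one
admission cohort: (1) deterministic rule evaluation over structured
hospitalization records, (2) human adjudication of flagged cases (recorded,
never inferred), (3) detection-performance metrics, and (4) downstream
statistics (risk factors, method comparison, and the Delphi statistics used
when the rule set itself is being designed).

An admission record carries demographics, stay dates, counts (comorbidities,
prior hospitalizations), the set of targeted PAH drug classes, and four
observation streams: laboratory values, medication exposures, coded clinical
events, and interventions. Units are fixed per analyte and the reader rejects
disagreeing unit columns rather than converting — silent unit conversion is
the classic pharmacovigilance failure mode. Length of stay is calendar days
floored at one (stays are ≥24 h by inclusion), the denominator unit of the
patient-day rate. Ages are fractional years (a 4-month-old is 0.33); the
minimum is 28/365, mirroring the cohort's ">28 days" criterion.

## Trigger rules and their conventions

The shipped rule set encodes the 24 validated triggers. Condition shapes:
absolute thresholds (optionally stratified by age/sex, e.g. the hemoglobin
bands), boolean composites (the hepatic rule: ALT or AST above 3× the upper
limit of normal, or bilirubin *and* ALP both above 2× ULN), baseline ratios
(BUN/creatinine rising above 2× the first in-stay value), drug-class
exposures resolved through the shipped dictionary, symptom-term sets
resolved through the controlled vocabulary, intervention kinds, and the
abrupt-cessation flag on a targeted drug.

Decisions that the published wording leaves open, fixed here:

- **Strict inequalities everywhere.** Thresholds are worded ">", "<",
  "more than"; a value exactly at the bound never fires.
- **Baseline = earliest in-stay measurement.** Pre-admission values are
  outside the data model, so the first value is the only defensible
  baseline; a rule needs ≥2 observations of the analyte to fire.
- **ULN values are configuration** (defaults ALT 40 U/L, AST 40 U/L, total
  bilirubin 21 µmol/L, ALP 125 U/L) since reference ranges are
  site-specific; they live in the rule-set YAML so sites can override
  without touching code.
- **Hemoglobin bands are half-open** ([6 mo, 5 y), [5, 12), [12, 15),
  [15, ∞) by sex); infants under 6 months are not evaluated for this rule.
- **Abrupt cessation is an explicit flag** on the exposure, not inferred
  from dosing gaps — no published inference rule exists, and inventing one
  would fabricate method.
- **Counting unit: one hit per (patient, trigger) per admission.** This is
  the only unit under which the published 472 trigger instances over 626
  patients (≈0.75/patient) and the per-trigger PPV denominators cohere.
- A note on totals: the published text says 375 patients "had positive
  triggers" while the confusion table reports 251 positive and 375 negative
  patients; the package follows the confusion table, which is the only
  reading consistent with the false-negative rate 2/375 being computed over
  negatives.

## Metrics

PPV is computed per trigger and pooled (Σ true ADEs / Σ positives — not a
mean of per-trigger PPVs). Sensitivity, specificity, and Youden's J are
patient-level. The "per 1,000 drugs" rate implements the conventional
printed formula, ADEs / Σ per-case medication types × 100; the name and the
multiplier disagree, and the package reproduces the formula as printed
rather than "fixing" it. The medication-type denominator is the cohort sum
of distinct targeted drug classes per case (1.93 × 626 ≈ 1,208). Undefined
ratios (zero denominators) surface as `None`, never as silent zeros.
Percentages are rounded half-up to two decimals to match printed tables.
Trigger-utility classes default to high ≥ 50% PPV, low < 20%, moderate
between — consistent with every labelled row of the validation table; the
two unlabelled rows fall where the defaults put them.

## Risk-factor analyses

Univariate screening is a Pearson chi-square (no continuity correction,
matching SPSS crosstab output) on each covariate's r×2 bin-by-ADE-status
table. The two published trigger-count binnings ("≥5" univariate, ">4"
regression) are retained as two named schemes; they partition integers
identically. The multivariable model is a maximum-likelihood binary
logistic regression with dummy coding against each scheme's first bin.
The model-fit statistic is Nagelkerke R²: the source reports an unnamed
"overall fit" of 0.589, and without the statistic's name we report the most
common SPSS pseudo-R² and note the ambiguity rather than asserting
equivalence. Perfect separation raises a structured error naming the
offending covariate. The paired GTT-vs-spontaneous comparison reports the
exact McNemar test (binomial on discordant pairs) as the primary result and
the plain chi-square on the same 2×2 for comparability with published
practice.

## Delphi statistics

Scores are bounded integers (default 1–5; the scale is configurable and
"full mark" means the scale maximum — the source does not state its range,
and 1–5 is the Delphi convention). Vj uses the sample (n−1) SD throughout.
Cut-offs are computed across items (mean−SD for Mj and Kj, mean+SD for Vj);
retention is non-strict (≥/≤) so that a degenerate panel with SD 0 retains
every item. An item failing all three criteria is dropped, passing all
three is retained, and anything mixed goes to discussion. Kendall's W uses
the tie-corrected formula over per-expert mid-ranks; a panel of constant
rows (zero information) returns W = 0. Cr = (Ca+Cs)/2 is the standard
authority formula; raw per-expert inputs must be supplied since only the
panel summary is published.

## The synthetic cohort

No patient-level data are deposited, so the generator is the package's
stand-in for the hospital extract. It emulates the published cohort
marginals: n = 626, male fraction 0.3914, age ~ truncated normal
50.04 ± 18.18 on [0.33, 93] years, LOS ~ lognormal moment-matched to
8.87 ± 8.08 and truncated to [1, 68] days, comorbidities and prior
admissions ~ shifted negative binomial matched to 5.74 ± 3.63 and
3.65 ± 3.55, targeted drug classes ~ 1 + Poisson(0.93) clipped to [1, 6].
Only moments and ranges are published; the distribution families are our
choice and are stated in the config. Covariates are drawn independently by
default (their correlations are unreported).

ADE status follows a logistic model over the binned covariates with default
betas equal to the log of the published odds ratios; the intercept is
calibrated by bisection so the realized mean risk hits the target
prevalence (default 0.1757). The positive-trigger count is deliberately
**not** a generating covariate: triggers arise downstream of ADE injection,
which reproduces the strong trigger-count association without circularity.
ADE patients draw 1 + Poisson(0.3) events (≈143/110); each event draws a
type from the published 19-type/nine-organ taxonomy, severity and causality
from the published distributions, and — with emission probability 0.98 —
injects the record feature that fires its mapped trigger (e.g. anemia
appends a sub-threshold hemoglobin; the published two undetected ADEs are
the motivation for the silent-ADE mechanism). False-positive noise fires
per trigger at marginal rates equal to the published false-positive counts
over 626, concentrated in a noise-prone 40% of patients so that
patient-level clustering approximates the published 329 FP instances over
141 FP patients. All randomness flows from one seeded generator; identical
seeds give identical cohorts byte-for-byte.

What the generator does *not* emulate: longitudinal lab physiology,
drug–drug interactions, correlated covariates, informative timing of
events within the stay, and real adjudication noise (ledger adjudications
are exact). Tests passing on synthetic cohorts therefore demonstrate that
the engine, metrics, and fits are correct relative to a known ground
truth — not that the rule set would achieve the same operating point on
another hospital's data.

## Problem sizes and numerical choices

The acceptance script uses 200 replicates of n = 5,000 for
parameter-recovery coverage and a 400-patient cohort for engine closure —
sizes at which Wald coverage and Monte-Carlo tolerances are stable while
the whole script completes in well under a minute. Bisection for the risk
intercept runs 200 iterations on [−20, 20] (far below float precision
limits). Logistic fits use statsmodels' Newton optimizer with a 200-
iteration cap; non-convergence is reported as a separation error rather
than returning unstable estimates.

## Known limitations

- Adjudication is bookkeeping: the package stores and reconciles human
  verdicts but contains no causality scoring (e.g. Naranjo).
- The published odds ratios cannot be reproduced exactly (patient-level
  data unavailable); the regression is validated by parameter recovery on
  synthetic cohorts instead.
- The symptom vocabulary is a flat code list with aliases — an abstraction,
  since the source system's symptom encoding is not described; free-text
  NLP extraction is out of scope.
- The printed Delphi panel values (cut-offs, Cr, W) cannot be recomputed
  without the raw expert scores; the module is validated on synthetic
  panels and degenerate cases with known answers.
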