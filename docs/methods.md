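# Methods

## Outcome definition

Histology is collapsed to one binary outcome, significant bowel disease
(SBD): cancer, ≥ 3 adenomas at procedure, largest adenoma ≥ 10 mm, villous
component, high-grade dysplasia, or IBD. The classifier short-circuits on
any qualifying finding, but a *negative* call requires every flag to be
present — incomplete histology raises `MissingDataError` rather than
passing silently as non-SBD. IBD is included in SBD (the inclusive
clinical reading: early IBD benefits from urgent colonoscopy exactly as
high-risk neoplasia does). Hyperplastic polyps, few/small low-grade
adenomas and normal colonoscopies are non-SBD.

## Categorization conventions

Printed reference brackets leave boundary conventions open; the package
fixes one set and applies it everywhere:

* reference intervals are **closed** — a value exactly on a bound is
  normal (`categorize_value(64, creatinine 64–108) → normal`);
* age is dichotomized at 65 years with the boundary counting as *older*;
* BMI brackets are half-open: `<18`, `[18, 25)`, `[25, 30)`, `[30, 40)`,
  `≥ 40`, so values in the printed gaps (e.g. 24.5) fall to the
  lower-adjacent bracket.

Missing values are explicit `None` sentinels end to end; they are excluded
pairwise from each 2×2 table (each marker keeps its own denominator) and
never imputed.

## Association machinery

* **Odds ratio** `(a·d)/(b·c)` with the Haldane–Anscombe +0.5 correction
  applied to *all* cells iff any cell is zero. This keeps
  perfect-association markers estimable during cross-validated screening.
  A table with an empty margin has no odds ratio and raises.
* **Confidence interval**: Woolf (log-normal) with z = 1.96. This choice
  exactly reproduces both published interval pairs from their printed
  counts (1.51–5.74 from (19,20,95,294); 4.29–18.75 from (28,11,86,303)),
  which is how the unstated method was identified.
* **p-values**: two-sided Fisher exact by default (exact conditional
  inference is appropriate at these cell counts); Pearson χ² on 1 df
  without continuity correction available by flag. An empty-margin table
  carries no evidence and returns p = 1.
* **Multiplicity**: Benjamini–Hochberg step-up. The high and the low level
  of one marker are two separate tests (each against the normal reading,
  with the opposite abnormal level excluded), entering one FDR family
  together with the binary stool tests, the age category and the symptoms.
* **Triage model**: baseline-category multinomial logit with category 3
  (least urgent) as reference, fitted by Newton–Raphson (gradient
  tolerance 1e-8, ≤ 200 iterations) via `statsmodels.MNLogit`; standard
  errors from the observed information, Wald p-values. Divergent
  coefficients (|β| > 20 on an indicator) or a singular information matrix
  are reported as separation, naming the predictor.

## Blood Risk Score

One point per marker whose value lies in its *scored* abnormal direction:
triglycerides high (> 1.5 mmol/L), glucose high (> 7.8), magnesium low
(< 0.7), creatinine low (< 64 µmol/L); capped at 4. Abnormality in the
unscored direction contributes nothing (high magnesium is not a point).
Missing markers contribute zero and are listed in the score's
`missing_markers` metadata so callers can audit partial panels.

## Risk-assessment tool

Two interchangeable modes over the features FIT-positive, age ≥ 65, BRS:

* **tree** — CART-style binary recursive partitioning on the ordinal
  encodings (binary features split at 1; BRS at 1..4), maximizing Gini
  impurity decrease. Defaults: `max_depth = 3`, `min_leaf = 10`. The
  induction is fully deterministic: candidate splits are scanned in
  feature order then ascending split point and only a strictly larger gain
  (beyond 1e-12) displaces the incumbent, so equal gains resolve to the
  earliest feature and lowest threshold. Leaves take the majority class;
  exact ties are labelled high-risk (the conservative direction for a
  triage tool). No pruning, surrogate splits or class priors.
* **fixed_rule** — a boolean expression over the same features, default
  `fit_positive and (age_older or brs >= 2)`. The default is a calibration
  choice: a FIT-gated conjunction is the simplest structure consistent
  with a tool that flags few patients at very high specificity. Rules are
  parsed into a restricted AST (boolean operators and comparisons only),
  so config-supplied rules cannot execute arbitrary code.

A record missing a needed feature at prediction time is returned
**low-risk with an audit flag**: the tool's value is its rule-in
character, so absence of evidence must not trigger urgent triage. Faecal
calprotectin is implemented as an optional feature but excluded from the
default feature set (its inclusion did not improve accuracy in the source
analysis).

## Evaluation

Leave-one-out cross-validation with in-fold selection: for each record,
the remainder is re-screened (blood panel only, FDR at the configured
alpha), the in-fold BRS is rebuilt from the markers whose scored-direction
level survived, the tree is re-grown, and the held-out record predicted.
A fold where no marker survives proceeds with FIT + age alone and is
counted in the report. Fixed-rule mode involves no training, so its LOOCV
is identical to direct application — a property the tests exploit.

The pooled confusion matrix yields sensitivity, specificity, PPV, NPV and
the OR with Woolf CI. Zero-denominator proportions — and the OR of a
constant predictor — are reported as *missing*, never as 0. The
comparator arm dichotomizes assigned triage into category 1 vs 2/3;
records missing the triage category are excluded from the comparator arm
only, records without histology from both arms.

Only the four named blood markers are eligible for the in-fold BRS by
default; wider panels can be passed explicitly.

## Synthetic cohorts

The generator emulates the study conditions: n = 467, 45.1% male, age
54.3 ± 13.8 (truncated normal on [20, 85]), BMI 27.8 ± 6.2, SBD prevalence
26%, FIT positivity 16.6% | SBD vs 6.4% | non-SBD, symptom frequencies per
the published SBD/non-SBD columns, calprotectin (0.30, 0.19) to match its
reported OR ≈ 1.8, and P(age ≥ 65 | SBD/non-SBD) = (0.354, 0.18), which
reproduces the reported age OR ≈ 2.5 at the cohort's ~22% older fraction.
The iron-deficiency-anaemia non-SBD frequency is set to 17.8% — the value
consistent with that row's published OR of 0.44 (the printed count is
internally inconsistent). Blood-marker abnormality pairs
(triglycerides (0.50, 0.40), glucose (0.22, 0.13), magnesium
(0.10, 0.055), creatinine (0.32, 0.26)) were chosen once as plausible
rates for an overweight symptomatic cohort that concentrate the BRS at low
scores with modest per-marker enrichment; they are calibration choices,
not published values. Default per-field missingness mirrors the published
per-variable denominators (histology 8.4%, triage 1.1%, BMI 3.4%, blood
2%, calprotectin 5%).

Variables are conditionally independent given SBD (only marginal and
conditional frequencies are published, so no correlation structure is
asserted); drawn SBD labels are guaranteed consistent with the constructed
histology (`classify_sbd(histology) == label`, asserted at generation).
SBD mechanisms are sampled with cancer at its low relative rate (~4.5% of
SBD), IBD 5%, and the four high-risk-adenoma mechanisms uniformly.
Within-category marker values are drawn uniformly on intervals strictly
inside/beyond the reference bounds — adequate for categorical analyses,
but the *continuous* marker distributions are not realistic. Missingness
is independent per field (no informative missingness), symptoms carry no
within-patient correlation, and triage assignment is a simple
multiplicative-weights model over symptoms. Passing tests therefore
demonstrate correctness of the machinery under the study's frequency
structure, not performance on real patients.

## Numerical and scale choices

* Determinism everywhere: one `numpy` generator seeded from the config;
  identical config + seed gives byte-identical cohort CSVs; tree induction
  and LOOCV contain no randomness.
* Odds-ratio recovery checks compare on the log scale (geometric mean):
  the sample log-OR is near-unbiased, while the arithmetic mean of ORs is
  inflated by Jensen's inequality at these cell counts.
* Monte-Carlo suite sizes — 60 screening seeds, 200 recovery cohorts,
  LOOCV convergence at n = 2000, exhaustive Fisher enumeration up to table
  total 40 — were chosen to keep the full suite in the low minutes while
  leaving sampling error well below the asserted margins (3 SE bands).
* Proportions are kept unrounded internally and rounded only at
  presentation (one decimal in percent).

## Known limitations

* The published decision algorithm's exact split structure is not
  recoverable from text, so the tree is induced from data and the fixed
  rule is explicitly a configurable default — neither is asserted to equal
  the original figure.
* At the study's effect sizes (FIT OR ≈ 2.9 with ~19 expected
  exposed-diseased counts), FDR-corrected screening has materially less
  than full power; single synthetic cohorts will sometimes select
  different marker subsets, and occasionally the tree flags no one
  (reported as missing OR). This is a property of the study conditions,
  not a defect of the implementation.
* No bootstrap CIs for sensitivity/specificity, no calibration curves, no
  ordinal (proportional-odds) triage model, and no modelling of waiting
  times or recruitment flow.
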