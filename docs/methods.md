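# Methods

This note documents the models, rules and numerical choices behind
`ncdcare`: what each component assumes, which parameters matter, and what
the synthetic cohorts do and do not emulate.

## Screening and triage

Every clinic attendee aged ≥ 30 is screened opportunistically.  Triage
partitions attendees into four groups — screen-positive hypertension,
screen-positive diabetes, known/follow-up, screen-negative — and known
status always dominates band classification.  The shipped band boundaries
are contemporaneous standard guideline cuts:

| measure | band | range | action |
|---|---|---|---|
| BP (mm Hg) | prehypertension | 120–139 / 80–89 | lifestyle counseling |
| BP | screen-positive | 140–160 / 90–100 | confirmatory revisit |
| BP | immediate | > 160 / > 100 | start management at once |
| BP | urgency | ≥ 180 / ≥ 120 | refer to higher centre |
| FPG (mg/dL) | prediabetes | 100–125 | lifestyle counseling |
| FPG | diabetes | ≥ 126 | confirmed (fasting sample) |
| random glucose | screen-positive | ≥ 140 | recall fasting |

The combined blood-pressure band is the more severe of the SBP and DBP
arms.  All bands are half-open `[lo, hi)` on an integer measurement grid —
the resolution of clinical sphygmomanometry — which is how "> 160/100" and
"≥ 140/90" coexist without gap or overlap: the screen-positive SBP band is
`[140, 161)` and the immediate band `[161, 180)`.  Every boundary lives in
the rule-set YAML, never in code; a revised guideline table drops in
without a code change.  The non-fasting screen cut of 140 mg/dL is the
package's own choice (standard practice for random glucose); non-fasting
values only ever trigger a fasting recall, never a diagnosis.

## The decision engine

`generate_plan` is a generic evaluator over the declarative rule set:
exactly one band template fires per condition, referred plans never
initiate drugs, every plan records the rule-set version, and the next visit
is always 3 months on.  A measurement outside the configured domain raises
an explicit "no rule fired" error; there is no silent default prescription.
Comorbid patients are evaluated under both rule families and the plans
merged — drug union ordered by an explicit precedence list, counseling
union, referral if either arm refers.

Titration is one-step-per-visit: above target (≥ 140/90 for BP, ≥ 126
mg/dL for FPG) the regimen advances exactly one ladder step — the current
drug's next dose, or the next ladder drug at its first step once the
current drug is at maximum.  The default ladders are amlodipine
(2.5/5/10 mg) → enalapril (2.5/5/10/20) → atenolol (25/50/100) for
hypertension and metformin (500–2000 mg) → glimepiride (1/2/4) for
diabetes, built from the generic formulary stocked at the programme's
pharmacies, with glimepiride as a rule-set-declared addition for the second
glycemic step.  Over-controlled patients are not auto-de-escalated; a
patient exhausting the ladder is flagged for physician review.  This makes
ladder position monotone in cumulative poor control, which the tests sweep
with randomized visit histories.

`validate_ruleset` is the machine analogue of scenario-testing a
decision-support tool: it evaluates every measure's domain at 1-unit
resolution, reporting values covered by zero bands (gap) or several
(overlap), ladder drugs missing from the formulary, and dose sequences a
one-step escalation cannot traverse.

The engine's input contract is 23 distinct data points per encounter (8
core measurement/demographic fields plus 15 history fields).  The shipped
list is a transcription-shaped schema: the analysis-relevant fields are
fixed, the history-field names are the package's own plausible rendering of
a nurse-led NCD encounter form.

## Clinic workflow

A visit walks registration → nurse screening (eligible first-time walk-ins
only) → plan generation → physician review → counseling → exit, in that
order, enforced by the episode invariants.  Physician behaviour is an
injectable policy `(plan, visit) → (decision, reason)`; shipped policies
are always-approve, always-reject, threshold-based disagree, and
Bernoulli(p).  A non-approved plan requires a documented reason and keeps
the patient's current regimen.  The agreement audit takes the first N
consecutive episodes per site (by visit order), pools across sites, and
reports the approved fraction with a disagreement-reason histogram —
pooling before the percentage, matching the audit's phrasing.

## Cohort generator

The generator's defaults are the study conditions: 6797 enrolled patients
weighted over 5 sites by the enrollment row sums (1625/588/1092/851/2641),
disease mix 5281 : 781 : 735 (hypertension-only : diabetes-only : both),
newly detected fractions 0.52 for hypertension and 0.30 for diabetes,
enrollment uniform over a 21-month window, visits on the
{0, 3, …, 18}-month grid.  A patient enrolled in calendar month *e* is
observed at follow-up *m* iff *e + m* ≤ 20: administrative censoring only,
so missingness is monotone by construction and about 3/21 of patients reach
the 18-month visit.  An attrition-hazard knob exists for sensitivity
analyses but defaults to 0.

Outcomes follow `y = μ(status) + δ(t) + u + e` with baseline means
149.1/143.0 mm Hg (SBP, new/known), 89.52 (DBP, both statuses — a
by-status split is not reported), 185.1/174.8 mg/dL (FPG), and marginal
standard deviations recovered by CI inversion: 15.8 mm Hg (SBP), 7.7
(DBP), 41.7 mg/dL (FPG).  The default change profiles δ(t) are the
observed unadjusted change columns (−12.9 … −14.6 for SBP, −31.5 … −50.2
for FPG); `effects_by_status=True` switches to the separate new/known
columns for interaction-recovery work.  Generation uses exchangeable
within-person correlation ρ = 0.5 — one concrete choice; the analysis
models need not match it, and that mismatch is precisely what the sandwich
variance must absorb.  Covariate effects (site, age, sex) default to zero
so adjusted and unadjusted analyses coincide unless deliberately switched
on.

Two physiological guards keep every generated row valid: DBP is capped at
SBP − 10 mm Hg (independent noise draws would otherwise cross in ~0.1% of
rows) and FPG is floored at 30 mg/dL.  Both act far in the tails and move
the means by far less than a baseline standard error.

What the generator does **not** emulate: informative dropout, medication
adherence dynamics, measurement rounding/digit preference, seasonal or
secular trends, and site- or clinician-level heterogeneity beyond optional
fixed offsets.  Recovery tests against this generator therefore demonstrate
*self-consistency* of generator + estimator — they cannot validate the
original cohort's effect estimates, whose micro-data are unavailable.

## Evaluation models

Change models are Gaussian GEEs with a binary indicator per follow-up
month, clustered on patient; β_t is the mean change at month t relative to
baseline.  Defaults per protocol: unstructured working correlation for
SBP/DBP, exchangeable plus Huber–White sandwich variance for FPG;
covariates (age, sex, site indicators) enter additively on request.
Interaction models cross the time indicators with newly-detected status
(reference: known) or disease group (reference: comorbid); per-group
changes are linear contrasts with variances from the robust covariance.
CIs are Wald, estimate ± 1.96 · robust SE.  No multiple-testing adjustment
is applied.  Estimation is delegated to statsmodels GEE; the module owns
scope filters (blood pressure among hypertension-or-both, glucose among
diabetes-or-both), design-matrix construction and contrast extraction.

Numerical choices: a failed GEE iteration raises a convergence error rather
than returning a dubious fit.  Noise-free (zero-residual) panels make any
working-correlation estimate degenerate; since the point estimates do not
depend on the working correlation there, the fit falls back to independence
weighting in that edge case.  On complete balanced data the saturated-time
GEE equals raw per-timepoint mean differences for every working
correlation — asserted to 1e-8 as the module's primary oracle.

## Problem sizes and tolerances

Stochastic checks are sized to be decisive yet quick: recovery of the
change profiles runs 50 replicate cohorts at full study scale (6016
hypertension / 1516 diabetes patients) and accepts within 3 Monte-Carlo
standard errors of the replicate mean; CI-coverage properties run 100–120
replicates at n = 300–400 with a 4-standard-error binomial band below the
nominal 95%; law-of-large-numbers checks on the generator run one draw at
n = 50 000 with 3·SE bands.  The physician-agreement audit averages 200
replicates of 5 × 100 episodes.  All randomness flows from explicit integer
seeds; identical seeds give identical panels, plans and episodes.

## Known limitations

The guideline transcription is provisional where the source tables are not
available verbatim (band edges, ladder order and dose steps are the
package's defaults, configurable in YAML).  The screening-yield input
counts carry an internal inconsistency in their source between the printed
known/new column labels and the prose's newly-detected fractions; the
simulator follows the prose (52% new hypertension, 30% new diabetes) and
the yield table exposes both labelings rather than resolving the conflict.
The evaluation is a pre–post design with no control arm: even perfectly
recovered change estimates are associations, not causal effects of the
intervention.
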