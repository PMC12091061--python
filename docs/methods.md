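# Methods

This note documents the statistical model behind each stage of the pipeline,
the conventions that required a decision, and what the synthetic data do and
do not establish.

## Outcome and eligibility

A visit is *retained* when attendance occurs on or before 28 days after the
scheduled date; otherwise it is an interruption in treatment (IIT). The
boundary is inclusive (28 days late → retained, 29 → IIT) and early
attendance — allowed up to 28 days before the scheduled date — counts as on
time. The analysis target attached to each visit is the IIT status of the
client's *next* scheduled visit; the last observed visit per client has no
target. Because the outcome needs a month to accrue and EMR capture lags by
roughly two more, visits scheduled less than three calendar months before the
database censor date are flagged ineligible, and a visit whose successor is
ineligible likewise has no target. A never-attended visit can still be
followed by a later scheduled visit (a re-engagement visit), which then
serves as its "next visit".

Time on ART is stratified in calendar months from the ART start date:
[0, 6] months, (6, 12] months, and beyond; exactly six calendar months is
still early ART. The first visit after initiation is flagged separately and
also counted in the 0–6 month stratum.

## Synthetic cohort generator

The generator emulates the data-generating process the analysis assumes, not
any particular clinic's records.

**Clients.** Covariates are drawn independently per client: sex (68%
female), age at ART start (lognormal, median 35 y, truncated to [16, 85]),
employment (45/45/10% employed/unemployed/unknown) with a payday on days
25–31 for the employed, household size (Poisson, mean 1.8 others),
travel time (gamma, mean 30 min), disclosure (70%), prior HIV testing
history (60%), readiness and testing-intent indicators, screening CD4
(gamma, mean 350 cells/mm³, present with probability 0.7), a phone-on-file
flag (85%) and a multi-facility ("shopper") flag (10%). A shopper flag is
generated as a plain Bernoulli covariate rather than by simulating
cross-facility movement.

**Visit process.** Visits are scheduled monthly (28 d) for the first three
visits and two-monthly (56 d) thereafter, anchored on the previous attended
date, until the scheduled date exceeds the follow-up horizon (default 14
months — a short post-initiation cohort; per-client visit counts then average
about seven). Each scheduled visit draws an attendance-delay category:
on-time/early, 1–3 d late, or 4–28 d late (conditional split from
`lateness_mixture`), or the >28 d disengagement event. A >28 d visit is
attended very late (29–84 d, probability 0.5) or never; after a
never-attended visit the client re-engages with probability 0.7, else drops
out of the observed record.

**Risk model and calibration.** The per-visit probability of the >28 d event
is `expit(α + Σ effects + noise)`: named covariate indicators times their
log-odds effects, plus client-level normal noise (SD 0.6) giving the
persistent heterogeneity that visit-history features can learn. The default
effect sizes are moderate (0.15–0.50 on the log-odds scale, largest for
young age and thin social support), consistent with the modest risk ratios
such cohorts show. The intercept α is solved so that the *population*
marginal rate of the event equals `base_iit_rate` (default 0.12, between the
11–14% range typical of these cohorts). The solve runs on a fixed internal
population sample of 8192 clients (its own random substream, independent of
`n_clients`), weighting each sampled client by their expected number of
realized visits — late-prone clients contribute fewer visits, both through
drop-out and because their anchored schedules fit fewer appointments into
the follow-up window; the expected schedule shift is folded into an
effective horizon. With null covariate effects the realized eligible-visit
IIT rate is unbiased for `base_iit_rate` (checked at n = 2000 clients within
two binomial standard errors).

Dynamic state multipliers (`archetype_multipliers`) act multiplicatively on
the odds once a client enters the *returning after disengagement* or *late
twice* state; they are excluded from the intercept calibration, so switching
them on raises the marginal rate above the base rate by design.

**Reproducibility.** One integer seed fans out through named
`SeedSequence` spawn keys into the calibration stream and independent
per-client streams, so identical configs give byte-identical CSVs and
enlarging the cohort reproduces the smaller one as a prefix.

**What the generator does not emulate:** inter-facility movement, seasonal
or facility-level effects, covariate correlation (age×employment etc.),
informative lab missingness, mortality and transfers-out, or true temporal
drift. Tests passing on this generator establish that the pipeline's logic
and statistics behave as specified under the assumed data-generating
process — not that the classifier would achieve any particular performance
on real records.

## Features

History features use strictly prior visits plus the current visit's own
lateness; labs use the most recent result at or before the visit; the next
appointment's calendar fields are known at the current visit (that is when
the appointment is issued). "Late" means more than 3 days after the
scheduled date; the >28 d counter shares the IIT boundary; never-attended
visits count as late under both. "Missed months" is the count of distinct
calendar months between the first and current visit containing no attended
visit. "Visits on regimen" counts the consecutive run of visits on the
current regimen code. Continuous month quantities use a 30.4375-day month;
the model's age feature uses exact fractional years, while archetype age
uses completed calendar years so that a 25th-birthday visit is "adult".

The EMR-only restriction drops the survey-collected columns (travel time,
household size, year first tested positive); CD4 and TB symptom count stay,
being routine clinical data. Encoding is deterministic: categoricals one-hot
with an `__other__` bucket for unseen levels, absent numerics imputed with a
−1 sentinel plus a missingness indicator column.

## Risk model

AdaBoost with depth-1 trees, 200 estimators, learning rate 1.0 (library
defaults for the algorithm; gradient boosting available as an alternative).
The training set is rebalanced to class parity by random down-sampling of
the majority class (up-sampling optional); the test set is never resampled.
The default split is at the visit level (clients may straddle sets),
mirroring the headline design; a client-level grouped split is provided as
the leakage-safe alternative, and a most-recent-months hold-out mimics
deployment. Confusion-matrix metrics are reported at a fixed 0.5 threshold
on the probability-like score (no threshold is optimized); AUC is
threshold-free. Feature importances are summed over derived (one-hot,
missingness) columns back to their source feature; top-k selection retrains
on the reduced set; bootstrap refits report per-feature top-k selection
frequencies and metric quantiles against a fixed test set.

## Threshold triage

Bins are assigned by the strict-below empirical percentile rank of each
score within the scored analysis set itself: green below the 0.50 cut,
yellow below 0.90, red above. Ties straddling a cut fall entirely into the
lower-risk bin (conservative: never inflates the red bin); an all-equal
score vector is entirely green with a warning. With 100 distinct scores the
split is exactly 50/40/10. A frozen-cutpoint mode (`TriageBinning.
score_cutpoints`) supports deployment-style scoring against stored cuts.
Visits without a next-visit outcome are excluded from triage tables.

**Doubling calibration.** The cutoffs originate from the criterion that each
bin's IIT rate should be about twice the bin below. The estimator grid-
searches percentile pairs (p₁ ∈ [0.20, 0.80], p₂ ∈ [p₁+0.05, 0.98], step
0.01) on the objective Σ(log(rate↑/rate↓) − log 2)². This objective alone is
weakly identified: for a three-plateau risk curve the population objective
is exactly zero along a whole line of cut pairs (moving the cuts trades
green and red mass into the yellow bin while preserving both ratios), and
for smooth curves it is near-zero over wide regions, so its plain argmin
wanders under sampling noise. The estimator therefore keeps every candidate
within 0.05 of the minimal objective — deviations of that order are
statistically indistinguishable at typical bin event counts — and among
these approximately-doubling candidates returns the pair maximizing the
binomial log-likelihood of the implied three-segment rate model, i.e. the
cuts best supported by the data's own rate structure. When the risk curve
truly has three rate regimes this coincides with the regime boundaries
(recovering the generating (0.50, 0.90) cuts at n = 5000 in ~95% of
replicates, median exact); otherwise it degrades gracefully toward the plain
minimizer. The search is deterministic, with ties resolved in grid order.

## Archetypes

Sixteen built-in rules: four mutually exclusive demographic cells (adult
female/male at ≥ 25 completed years; AGYW/ABYM at 15–24 — age exactly 25 is
adult, avoiding a gap), four behavioral and eight socio-behavioral profiles.
Operationalizations, all configurable module constants: "on time" reuses the
3-day lateness boundary; "regularly prompt" requires at least two prior
visits all ≤ 3 d late, "regularly late" at least two prior visits > 3 d
late; "lives alone" means zero other household members, "alone or with one
other" ≤ 1; travel-time splits are strict at 20 minutes (exactly 20 matches
neither side); the payday window is < 7 days between the next appointment
and the nearest monthly payday (clipped to month length); "returning after
disengagement" means any prior visit more than 28 d late or never attended,
a state that persists for all subsequent visits. Rules needing survey fields
simply do not match clients lacking them, with the skip logged. Risk tables
compare each archetype against its category's reference (adult females;
prompt-and-loyal; super-green), optionally crossed with the demographic
cells and/or restricted to the first six months on ART.

Segment discovery reproduces the procedure that motivated the rules:
enumerate every value configuration of every pair (order configurable) of
discretized key variables, drop configurations observed in no visit
(including logically unsatisfiable combinations) and segments below
`min_size` (default 50 visits), and rank the rest by absolute departure of
their IIT rate from the population baseline.

## Relative risks

Crude RR with the Katz log-method CI, no continuity correction: a reference
group with zero events is an error and a zero-event exposed group yields
RR = 0 with an undefined interval. Estimates stay at full precision;
rendering rounds half-up to two decimals (rates to whole percent). Repeated
visits per client are not adjusted for — the crude design is intentional and
inherited, and CIs for within-client-correlated visit data are accordingly
anti-conservative; a known limitation.

## Problem sizes and numerical checks

The test suite runs small cohorts (300 clients shared across tests, 2000 for
calibration and monotonicity properties, 5000 for discrimination and
doubling-recovery checks; 500-client end-to-end runs executed twice for
byte-identity). The stats oracle compares `crude_rr` against an independent
plain-Python log-method implementation to 1e-12 on 1000 random tables, and
the CI's empirical coverage is measured at 2000 simulated null tables of
group size 2000, where the nominal 95% level applies; at smaller group sizes
(e.g. 500) the Katz interval is measurably conservative (~95.1%). The
doubling-recovery check uses the median over three replicate draws at
n = 5000 to keep a stochastic estimator's check stable.
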