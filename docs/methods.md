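# Methods

## The measurement model

All three test families target a monthly discount factor d ∈ (0, 1]: the
value today of $1 delivered one month later. The *near* variant of each
test offers the smaller-sooner (SS) reward today; the *far* variant adds a
30-day front-end delay to both options, so the near/far contrast isolates
nonstationarity (a change in expressed patience when the whole scenario is
pushed into the future). Scores are oriented so greater = more patient.

### Probabilistic bisection

The adaptive test maintains a discretized posterior over d on an equispaced
1024-point grid spanning [0, 1] (resolution ≈ 0.001, far below the
dollar-rounding resolution of the stimuli, which is about 1/95). Each
scored trial draws the larger-later (LL) amount uniformly from $15–$95 and
sets SS = round(median · LL), clamped to [1, LL−1] so every item remains a
genuine tradeoff. The update conditions on the *stimulus actually shown*:
the effective query point is the rounded ratio SS/LL, not the pre-rounding
posterior median. Choosing LL signals d above the query point, so the grid
mass above it is rescaled to total p_c and the mass at/below to 1 − p_c
(the classical multiply-by-2p_c update is the special case of querying
exactly at the median). p_c = 3/4 is the assumed probability that the
respondent chooses the option they on average prefer. The posterior median
is defined grid-exactly as the smallest support point with cumulative mass
≥ 1/2; the test's score is its final value.

Degenerate updates (all mass already on one side of the query) are no-ops
with a warning rather than errors: they can legitimately arise when a run
of consistent answers pushes the posterior to a boundary.

Two catch trials with amount ratios 0.07 (LL overwhelmingly better) and
1.13 (SS strictly dominant: sooner *and* larger) are interleaved at seeded
uniformly random positions among the 22 slots. They never update the
posterior; choosing the designated wrong option increments a failure
counter used by the exclusion rules.

### Fixed items and matching

The fixed test ships the medium-magnitude items of the standard 27-item
monetary choice questionnaire as an editable default bank, ordered by the
hyperbolic discount rate at which SS and LL are indifferent
(k = (LL − SS)/(SS · Δt)). Scoring enumerates candidate indifference ranks
r ∈ {1, …, K+1}, where candidate r predicts LL on exactly the r−1
highest-rank (steepest-tradeoff) items; the subject's rank is the
arithmetic mean of the argmax set (ties of three or more non-adjacent
candidates are how non-integer scores arise), and the reported score is
a·rank + b with (a, b) = (2, −2) by default. Both K and the affine
transform are configuration: published descriptions of this scoring are
ambiguous about the item count behind the printed score range, so the
package exposes the choice instead of hard-coding one reading.

Matching trials draw SS uniformly from $1–$95 and record the free-response
LL amount at cent precision. Responses with LL < SS are flagged as errors
but still enter the score (the median of SS/LL ratios, midpoint convention
for even counts); the flags feed the exclusion accounting, mirroring how an
analyst would count rather than silently drop them.

## The synthetic respondent

The generator defines the study conditions; it is deliberately simple and
fully seeded.

* d_near ~ Beta(3.5, 1.5) (mean 0.70, median ≈ 0.73, quartiles ≈ 0.58/0.85),
  a realistic spread for monthly discount factors on crowdsourced samples.
* A configurable fraction (default 0.8) of subjects is nonstationary:
  d_far = d_near + Normal(−0.02, 0.15), clipped to (0, 1]. The small
  negative shift encodes the mild empirical tendency to plan to be *less*
  patient later; the rest have d_far = d_near exactly, which is what makes
  the "stationary" category non-empty for coarse scores.
* Choices follow "prefer LL iff d·LL > SS, comply with probability
  choice_consistency" (default 3/4, matching the bisection test's assumed
  p_c). Exact indifference is resolved by a fair coin — unbiased and
  directly testable.
* Catch trials use a separate, much smaller error rate (default 0.05):
  attention lapses on dominated items are rarer than inconsistency near
  indifference, and a single compliance parameter would exclude a third of
  any simulated cohort under the ≥3-of-8 rule.
* Matching responses are SS/d times lognormal noise with log-sd 0.05
  (median 1, so the response median inverts exactly), rounded to cents.
  The symmetric jitter occasionally crosses below SS for very patient
  subjects; this is what produces realistic counts of flagged trials,
  though it over-produces them relative to human data, where boundary
  errors come from carelessness rather than symmetric noise.
* Criterion coupling runs through a single standardized latent trait
  z = Φ⁻¹(F_Beta(d_near)) — exactly standard normal and perfectly
  rank-correlated with patience. Each binary criterion is a thresholded
  Gaussian latent sign·√λ·z + √(1−λ)·ε whose loading λ solves
  (Φ₂(m, m; λ) − Φ(m)²)/(Φ(m)(1 − Φ(m))) = effect_size with
  m = Φ⁻¹(positive rate): the population Efron's R² of the probit of the
  criterion on z equals the configured effect size exactly, at any base
  rate. Continuous criteria carry variance share λ = effect_size on their
  analysis scale. effect_size = 0 makes every criterion independent of all
  latents, the null condition used for the association-without-prediction
  demonstration. The default effect_size is 0.03, the scale reported for
  such criteria in this literature.
* Study-2-style patience pairs are zero-inflated (default 10%, independent
  of the latent, modelling "no extra amount needed" as a response style),
  otherwise lognormal (log-mean 5.0 for the month item, +log 4 for the
  year item, log-sd 1.5) with variance share 0.5 on z, rounded to one
  significant figure. The rounding matters: people answer with round
  numbers, which is what keeps the distinct-pair count in the hundreds
  (≈ 760 distinct pairs, ≈ 180 singletons at n = 7,127) and gives the
  nominal class model its characteristic structure. The 40-column
  criterion block uses 32 binary criteria with base rates spread over
  0.51–0.95 and 8 heavy-tailed continuous ones, all coupled through the
  same calibrated-loading scheme.

What the generator does *not* emulate: panel attrition, self-presentation
bias, memory for earlier answers (which inflates real retest reliability
for fixed items), domain-specific patience, or any behavioral model richer
than constant-probability compliance. Passing tests therefore certify the
*machinery* — scoring, coding, cross-validation, the overfitting contrast —
under a plausible respondent, not that real human tables are reproduced
numerically.

## Criterion coding and exclusions

Codings are declarative rules: exercise hours → log(x+1); percentage items
→ clip to [0.005, 0.995] then logit; BMI = kg/m², dichotomized at ≥ 25
(closed at 25); count items dichotomized at > 0; flossing → three ordered
categories (0, 1–6, ≥ 7 per week); credit-card rules apply to cardholders
only; cigarette packs (smokers only, log scale) is the tenth criterion
alongside the nine questionnaire-based ones. "Nonsense answers" are
operationalized as out-of-domain values — negative counts, percentages
outside [0, 100], height/weight/age outside configurable physiologic
bounds — since no principled universal definition exists; the bounds are
configuration.

Exclusion follows the three-rule scheme with a documented session log as
input: nonsense answer, ≥ 3 failures of the 8 session-1 catch trials, or
≥ 3 of the 40 session-1 matching trials with LL < SS. The retest sample
additionally drops subjects completing session 2 in under 3 minutes. The
report deduplicates overlapping reasons.

## Association versus prediction

Cross-validation uses seeded, unstratified, balanced folds (sizes differ by
at most one); each case is predicted exactly once by a model whose training
folds exclude it. Training folds that go degenerate (single-class outcome,
quasi-separated probit, collinear design) fall back to an intercept-only
fit and are logged rather than aborting the run — with 9-term designs on
zero-inflated predictors this is a live possibility, and a crashed fold
would bias the comparison.

Metric conventions: continuous criteria use in-sample R² against
out-of-fold RMSE with the population SD as baseline; binary and ordinal use
Efron's R² (for ordinal, an Efron-style statistic on the expected category
index with categories coded 0, 1, 2) against out-of-fold proportion correct
with the modal base rate as baseline; median-loss models use MAE against
the mean absolute deviation from the median. Point predictions for
discrete outcomes are argmax-probability classes. PVAF uses the population
(divide-by-n) variance of the target so self-prediction of identical scores
is exactly 1. Ordinal probit absorbs the intercept into its thresholds, so
constant design columns are dropped for that family.

The nominal class model memorizes: each distinct patience pair is a class,
training singletons pool into one class, per-class predictions are the
training mode (binary, ties broken by the global mode, residual ties to the
smaller coded value) or median (continuous). A pair unseen in training
routes to the pooled singleton class when one exists — it is the model's
"rare response" pool — else to the global fallback. Its in-sample fit
dominates the 9-term log model by construction on the shared partition; the
out-of-fold comparison is where the overfitting shows.

Rank-sum tests use midranks; the exact branch enumerates all assignments
(used automatically at pooled n ≤ 12, available on request beyond), the
large-sample branch uses the tie-adjusted normal approximation with
continuity correction. Enumeration puts the approximation's worst-case
error at 8-per-group near 0.011 without ties and a few hundredths under
heavy ties — adequate for screening, which is why the automatic threshold
stays conservative and exact. Holm correction is the standard step-down
procedure, with the declared family size allowed to exceed the number of
supplied p-values.

## Problem sizes and numerical choices

The simulation studies in the test suite use the study-scale conditions:
181 subjects and 10 criteria over 100 replicates for the null
association-without-prediction pattern, and 7,000 subjects, 40 criteria and
20 seeds for the log-versus-nominal contrast; bisection recovery uses the
full d ∈ {0.1, …, 0.9} sweep at 20 trials on the 1024-point grid and 500
simulated subjects for retest stability. Posterior normalization is
maintained to 10⁻¹² after every update. All randomness flows from a single
integer seed fanned out via counter-based child generators
(`default_rng([seed, stage, subject, round])`), so every stage is
independently reproducible and pipeline reruns are bit-for-bit identical.

## Known limitations

* The respondent model is a stand-in: no claim is made that simulated
  descriptive, reliability or nonstationarity tables match any particular
  human dataset numerically.
* The choice rule ignores the absolute delays of fixed items (it compares
  d·LL to SS for any item), which is consistent with the one-month
  structure of the bisection and matching tests but coarse for item banks
  with heterogeneous horizons.
* Efron's R² for the ordinal family (expected-category-index version) is
  one of several reasonable conventions; alternatives would shift values
  slightly but not the association/prediction contrast.
* Exploratory learners (k-NN, SVMs, kernel regression, random forests) and
  parametric discounting models (hyperbolic k) are out of scope by design:
  the object of study is tests and their evaluation, not models of
  intertemporal choice.
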