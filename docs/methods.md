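# Methods

`acsmarkov` implements a single-cycle Markov (decision-tree) model of
hospital-based addiction consult service (ACS) care for patients
hospitalized with opioid use disorder (OUD), together with the full
estimation pipeline that would populate it from claims-style data: cohort
construction, expert-elicited beta priors, Bayesian logistic regression
transition models, and expected-count projections with deterministic
uncertainty bounds.  This note records the model, the estimation choices,
and what the synthetic-data experiments do and do not demonstrate.

## The care-pathway model

A patient admitted with OUD passes through three stochastic branch
points over a single 12-month cycle:

1. **ACS referral** during the admission, with probability `p_ref`;
2. **post-discharge treatment engagement** — a claims-measurable proxy
   for entering medication treatment — with probability `p_eng|ref` if
   referred and `p_eng|noref` otherwise;
3. **12-month outcome**: drug-related death, non-drug-related death, or
   survival, with cause-specific death probabilities that depend on
   engagement status.

All states at 12 months are absorbing and there are no recurrent
transitions, so expected state occupancy for a closed cohort of size *N*
is closed-form:

```
f        = p_ref * p_eng|ref + (1 - p_ref) * p_eng|noref
E[deaths_c] = N * (f * p_c|eng + (1 - f) * p_c|noeng),   c in {drug, non-drug}
```

Two conventions for the engaged fraction coexist deliberately, because
the study being reproduced uses both: the expected **engaged count** uses
the not-referred engagement probability alone (`N * p_eng|noref`), while
expected **deaths** use the combined two-branch fraction `f`.
`engaged_fraction()` exposes both via its `convention` argument and the
projection functions default to the convention each printed quantity
requires.  The mismatch is a property of the source estimates, not of
this implementation, and we reproduce rather than resolve it.

### Low/High bound scenarios

Uncertainty in projections is carried as deterministic endpoint
combinations, not a probabilistic sensitivity analysis.  The **High
death** scenario takes referral and engagement at their *lower* 95%
bounds and mortality at its *upper* bounds (fewest patients reach
protective treatment, mortality at its worst); **Low death** is the
mirror image.  The ordering `low <= point <= high` for every projected
quantity is guaranteed when the probability set respects the model's
structure — referral improves engagement and engagement is protective,
bound-wise (`p_eng|ref >= p_eng|noref` and `p_death|eng <= p_death|noeng`
at each of point/lower/upper).  Sketch: under those orderings the
combined fraction `f` is monotone in each branch probability, so the
High-death combination minimises `f` while maximising both conditional
death probabilities, and the per-person death rate
`f*p_eng + (1-f)*p_noeng` is decreasing in `f` when engagement is
protective.  For fully arbitrary valid probability sets the inequality
can fail (an engagement-harmful corner inverts the scenario logic), so
the randomized property tests draw structured sets.

### Rounding

Study-cohort expected counts are reported to one decimal.  External
count projections follow the published convention: the point estimate to
one decimal (or truncated, per quantity), Low/High bounds truncated
toward zero.  Rates per 100 person-years (each cohort member treated as
one person-year at risk) are reported to one decimal.  Probabilities
enter all projections at full precision; nothing is rounded
intermediately.

## Cohort measures

* **Eligibility** — adults (>= 18) with an ICD-9 `304*` or ICD-10 `F11*`
  diagnosis on an admission inside the study window (2015-04-01 through
  2018-08-31, integer day offsets from the 2015-04-01 origin).  The
  *index* admission is the first eligible one; patients admitted on or
  before 2018-01-01 form the mortality cohort (12 months of follow-up).
* **Engagement** (modified HEDIS) — clause (a): >= 2 fills of
  buprenorphine, XR-naltrexone, or OTP methadone with fill date in days
  1..30 after discharge (day 0 is the discharge day and is excluded);
  clause (b): buprenorphine/XR-naltrexone supplied days overlapping the
  window, summed across fills and capped at 30, reach >= 28.  Methadone
  counts only toward clause (a): it is dispensed per-visit through
  opioid treatment programs and has no meaningful days-supply.
* **Death classification** — deaths within 365 days of the index
  discharge are drug-related if the underlying-cause code starts with a
  configured prefix (default X40–X44, X60–X64, X85, Y10–Y14: accidental,
  intentional, assault, and undetermined poisoning); per-patient
  overrides stand in for manual chart review.  Everything else is
  non-drug-related; no death record within the window means survival.
* **Matched controls** — up to 3 (configurable) non-referred controls
  per referred case, exact on (admission calendar quarter, admission
  number), without replacement.  Determinism: cases in ascending
  admission-date order, controls within a stratum in (admission date,
  patient id) order.

## Expert elicitation

Per vignette, expert probability ratings are summarised by mean, min,
and max.  Beta priors are fitted at a configurable strength:

* **sample-size method** — `alpha = m*f*N`, `beta = (1-m)*f*N` for
  fraction `f` in {0.1%, 1%, 5%, 10%} of the cohort size `N`; the
  effective prior sample size `alpha+beta = f*N` holds exactly.
* **confidence-interval method** — `[min, max]` is read as the central
  interval at level {80, 85, 90, 95}%.  The mean is a hard constraint
  (`beta = alpha*(1-m)/m`), leaving a deterministic 1-D minimisation of
  the squared endpoint discrepancy over `log alpha` (coarse 400-point
  grid, then bounded refinement at 1e-10 tolerance).  One free parameter
  generally cannot hit two asymmetric endpoints exactly; fits whose
  endpoints miss by more than 1e-3 carry `feasible=False` rather than an
  error, since the best-fitting member of the constrained family is
  still a usable prior.

Priors enter regression models as **pseudo-data** (a power-prior-style
bridge): a vignette's Beta(alpha, beta) contributes `alpha` successes and
`beta` failures at the vignette's covariate profile, with unspecified
covariates held at the observed means.  This choice — the elicitation
literature offers no canonical mapping from vignette-level beta priors
to coefficient priors — keeps the prior on the probability scale the
experts answered on and makes its weight (`sum of alpha+beta`) directly
interpretable as pseudo-patients.

## Bayesian transition models

Each transition is a logistic regression on the shared covariate list
(age, gender, race (White / not White / unknown), Hispanic ethnicity,
alcohol and stimulant use disorder, length of stay, rural residence,
MOUD fill in the 30 days before admission, prior admission, CDPS
comorbidity score), plus referral for the engagement model and
engagement + post-discharge naloxone fill for the two mortality models.
The "kerman" reference prior adds Beta(1/3, 1/3) worth of pseudo-data at
the covariate-mean row — Kerman's neutral prior on a probability, which
keeps the posterior proper under separation while staying near the
maximum-likelihood fit; `"flat"` adds nothing.

**Sampler.**  Adaptive random-walk Metropolis: the chains start at the
(pseudo-data-penalised) maximum-likelihood estimate from a weighted
binomial GLM, proposals are Gaussian with covariance `(2.38^2/d)` times
the Laplace approximation, and each of the 4 chains' global step scale
adapts toward 30% acceptance during burn-in only (diminishing nothing —
the post-burn-in kernel is fixed, so the retained draws are a valid
Markov chain).  `n_draws` is the total retained across chains (default
10,000, burn-in 2,000 per chain).  If the initial MLE fails (complete
separation under a weak prior) the sampler falls back to a unit-scale
start and flags the fit.  Identical data, spec, and seed give identical
draws.

**Diagnostics.**  Rank-normalised split R-hat, bulk effective sample
size, and lag-k autocorrelations per parameter (via `arviz`), with
pass/fail thresholds R-hat < 1.01 and ESS > 1,000.  A random-walk chain
has autocorrelated draws, so reaching the ESS threshold at default
settings requires the full 10,000-draw budget; the test suite runs
smaller chains and checks diagnostics on constructed draws instead.

**Model comparison.**  PSIS-LOO expected log predictive density over the
*observed* rows only (pseudo-data is prior, not data), with higher elpd
ranked better and any Pareto k >= 0.7 flagging an unreliable estimate.

**Marginal probabilities.**  For each posterior draw, the inverse-logit
linear predictor is averaged over the observed covariate rows —
optionally with one covariate forced to a level for every row (e.g.
engagement probability "given referral") — and the draw-level averages
are summarised by mean and central 95% percentile interval.

## Synthetic data

The generator emulates the merged claims / referral-registry / vital-
statistics structure: covariate marginals match the published cohort
(age 44.5 ± 15.4 truncated at 18; 43% male; 70.1/6.4/23.5% White / not
White / unknown race; 3.5% Hispanic; 3.6% AUD; 8.2% stimulant use
disorder; log-normal length of stay with mean 6.6 days; 26.4% rural;
17.8% MOUD at admission; 22.4% previously admitted; gamma CDPS with mean
2.5, SD 1.6; 5% post-discharge naloxone — the one covariate whose
cohort prevalence is not published).  Referral, engagement, and death
are Bernoulli draws from logistic models whose default intercepts put
the marginals near the published transition probabilities (4% referral,
20%/47% engagement, ~15% 12-month death among the non-engaged) and whose
slopes are modest values on the raw covariate scale; a death is
drug-related with probability 0.30 if engaged and 0.40 if not (the ratio
implied by the published conditional death probabilities).

Event tables are constructed to make the latent truth exactly
recoverable: engaged patients get either two qualifying fills (days 5
and 20 post-discharge) or one 30-day supply on day 1, exercising both
HEDIS clauses; non-engaged patients get zero fills or one short fill
that satisfies neither clause; prior admissions carry non-OUD codes so
the OUD admission stays the index; drug and non-drug deaths draw codes
from disjoint configured sets.  Dates are integer day offsets from
2015-04-01.

What this does **not** emulate: covariate correlation structure (the
source reports only marginals, so covariates are sampled independently),
realistic ICD code frequencies, enrollment gaps, multiple index
admissions, or measurement error in the claims-derived flags.  Passing
the recovery tests therefore shows the measures layer inverts its own
generating rules exactly — a correctness check on the classifiers, not
evidence about misclassification in real claims.

## Problem sizes and numerical choices in the test suite

The test and acceptance runs use sizes chosen to make each check
statistically decisive on one CPU: 4,000-patient cohorts for truth
recovery and matching; a 12,000-patient cohort for the flat-prior vs
maximum-likelihood comparison (at smaller sizes the genuine O(1/n)
posterior-mean-vs-mode offset in sparse cells — e.g. AUD x referral —
exceeds Monte-Carlo error, which is the quantity the 3-MCSE tolerance
measures); 100 replications at n = 5,000 with 2,000 retained draws for
95%-interval coverage; 40 replications at n = 1,000 for the LOO
noise-covariate comparison (the chi-square-scale elpd signal does not
grow with n, so the smaller size loses nothing); 100,000 individuals for
the microsimulation-vs-algebra check; 1,000 randomized probability sets
for the conservation/bound-ordering property.  The LOO comparison's
theoretical win-rate ceiling is P(chi2_1 < 2) ~ 84% — an exact-posterior
oracle reaches 33/40 at these conditions — so the test requires wins
>= 28/40 (far above chance) plus a negative mean elpd penalty, rather
than a rate the process cannot reliably deliver.

## Known limitations

* The single-cycle structure cannot represent time-varying engagement or
  repeated admissions; it is a decision tree wearing Markov clothing,
  faithful to the source model.
* Low/High scenarios are bounds under monotone structural assumptions,
  not credible intervals; they over-cover relative to a full
  probabilistic sensitivity analysis.
* The random-walk sampler is adequate for the ~15-parameter logistic
  posteriors here but autocorrelates; users wanting ESS near the draw
  count should raise `n_draws` rather than reading precision off the
  default.
* The pseudo-data prior bridge attaches each vignette's weight at a
  single covariate row; elicitation designs whose vignettes vary
  covariates the model omits will silently project onto the model's
  span.
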