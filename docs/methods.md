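# Methods

## The estimation problem

A 5-year survival risk model `h(t) = h0(t) exp(βX·X0)` developed on a long
calendar window absorbs the window-average event hazard into `h0`.  If the
hazard carries a calendar trend `exp(γT·T)`, predictions for subjects
entering after the development window are miscalibrated by roughly
`exp(γT·Δ)`, where Δ is the calendar gap between the effective development
period and the new subject's entry.  Adding calendar time at entry,
`h(t) = h0(t) exp(βT·T0 + βX·X0)`, identifies `βT = γT` exactly when the
true hazard is proportional in calendar time: on the time-from-entry scale
`exp(γT(T0 + t))` factors into `exp(γT·T0)` times a `t`-only term absorbed
by the baseline hazard.

The confounded question is whether the trend is *direct* or operates
through treatment drop-in — statin initiation during follow-up that rises
over calendar time and lowers event rates causally.  Time-varying
covariates that drive both initiation and events make naive adjustment for
treatment status invalid, so the package fits a marginal structural Cox
model (MSM): person-time is re-weighted by stabilised inverse-probability-
of-treatment weights so that, in the pseudo-population, initiation is
unconfounded given baseline covariates, and the weighted fit of
`h(t) = h0(t) exp(βA·A_t + βX·X0 [+ βT·T0])` has a causal reading for
`βA` and supports never-treated counterfactual risks
`E[Y(Ā=0)|X0] = 1 − exp(−H0(5) exp(βX·X0 [+ βT·T0]))`.
If calendar time reaches the outcome only through drop-in, the MSM's
direct calendar coefficient is zero.  This rests on exchangeability
(no unmeasured confounders of initiation — true by construction in the
simulator), positivity, consistency, and correct specification of both the
outcome and weight models.

## Weight construction

Follow-up is discretised at ten 6-month time points; `A_k` is the
treatment status at time point k (`A_0 = 0` by cohort definition, and
treatment is absorbing).  Two interval-censored Cox models are fitted to
the untreated person-time: a denominator model on time-varying plus
baseline covariates and a numerator model on baseline covariates only
(plus `T0` whenever the outcome model includes it).  Each is converted to
a per-interval conditional initiation probability through its Breslow
baseline: `p = 1 − exp(−ΔH0(k)·exp(lp))` with `ΔH0(k)` the baseline
cumulative-hazard increment across interval k.  The stabilised weight
carried by the outcome row for interval K is the product of transition
factors for the statuses `A_0 … A_K` — `p*/p` at the initiation
transition, `(1−p*)/(1−p)` otherwise.  The transition unfolding *within*
a row's own interval is deliberately excluded from that row's weight: its
observation may be cut short by the event, and including such partially
observed factors measurably biases `βA` (this was verified by comparing
against weights built from the generator's true probabilities).  Weight
models use first-order fractional-polynomial terms only by default, a
parsimony choice mirroring the practice of pruning weight-model terms that
produce extreme weights; percentile truncation is available but off by
default, so the weight definition is used literally.

## The synthetic cohort generator

Subjects enter uniformly on a calendar window (default 1998–2015,
years measured from the window start with 365.25-day years).  Continuous
covariates are Gaussian at entry and follow a Gaussian random walk across
the half-year grid; binary and categorical covariates are fixed.  Within
each 6-month interval, covariates and calendar time are frozen at the
interval start and event/initiation/censoring times are drawn by
inverse-CDF exponential sampling from

    h_event = h0_event · exp(Σ βj (x_jk − ref_j) + γT·(T0 + k/2) + βA·A_k)
    h_init  = h0_init  · exp(Σ αj (x_jk − ref_j) + γI·(T0 + k/2))   (while untreated)

Effects apply to covariates centred at a reference value (default: the
mean), so the baseline hazards describe a reference subject — a pure
reparameterisation chosen for numerical interpretability.  Two
conventions deserve emphasis:

- **Treatment onset.**  A statin initiated during an interval starts
  affecting the event hazard at the *next* half-year point.  This models
  a prescription-to-effect lag aligned with the review grid and makes the
  discrete `A_k` exposure representation exact, so the estimand the
  interval analysis targets is the estimand the generator defines.  With
  instantaneous onset, the fixed grid misclassifies an expected three
  months of treated exposure per initiator and attenuates `βA` by ≈ 0.04
  at the shipped event rates.
- **Paired worlds.**  The generator consumes a fixed number of random
  draws per subject-interval regardless of state, so two scenarios
  sharing a seed but differing in hazard parameters (e.g. initiation
  disabled) are draw-for-draw paired.  Counterfactual checks compare the
  MSM's never-treated risk against the *observed* incidence of the
  paired untreated world.

`analytic_incidence` integrates the same piecewise-constant hazard in
closed form and serves as the generator's independent oracle.

Missingness is MCAR or MAR-on-age, at either the subject-timepoint level
(sporadic gaps, closed by LOCF/NOCB) or the subject level (a variable
never measured for a patient — the pattern that exercises the stochastic
baseline imputation).  True values are retained alongside the mask so
imputation can be scored against truth.

What the generator does **not** emulate: deterministic ageing, coding
artefacts and register churn of real primary-care data, treatment
discontinuation, and dependence of covariate drift on health status.
Passing tests therefore demonstrate estimator correctness under the
stated data-generating assumptions, not robustness to real-EHR messiness.

## Cohort derivation

Eligibility excludes pre-entry events or statin prescriptions; follow-up
is truncated at the earliest of random censoring, the study end, and five
years.  The development/validation split censors development follow-up at
the calendar cut date (default 2010-01-01), with an event exactly on the
cut treated as censored (exclusive boundary).  The counting-process table
holds one row per subject per 6-month interval at risk; `treat` reflects
initiation strictly before the interval start, and person-time is
conserved exactly (the final row stops at the exit time).

The reverse-causation guard — an initiation followed by the event within
6 months is discarded — is applied by default, as in observational
practice where the prescription may have been triggered by the impending
event.  On synthetic data this guard *creates* bias (≈ −0.1 on `βA` at
the shipped rates) because it selectively deletes genuine early-treatment
events; it is therefore a configurable flag (`near_event_rule`), and the
causal-recovery analyses disable it while the default study pipeline
keeps it.

## Imputation

Stage 1–2: within-subject LOCF then NOCB on the 10-point grid.  Stage 3:
one stochastic chained-equations imputation at baseline for variables
missing at every time point — Bayesian linear draws (posterior scaled-
inverse-chi-square sigma, normal coefficients, residual noise) for
continuous variables, logistic draws with coefficient-uncertainty
sampling for binary ones, marginal donor draws for categorical; 10
cycles, visit order by ascending missingness.  Every imputation model
includes all other covariates, the Nelson–Aalen cumulative hazard at the
subject's exit, and the event indicator.  Imputed baseline values are
copied to all later time points.  A single completed dataset is produced;
observed values are never altered.

## Estimators and numerics

The in-package Cox fitter maximises the weighted partial likelihood on
counting-process rows (risk set `start < t ≤ stop`, so delayed entry is
native) by Newton–Raphson with step-halving; convergence at
`max|score| < 1e−9` or relative log-likelihood change `< 1e−10`, error
after 100 iterations.  Efron tie handling (weighted form) is the default,
Breslow available.  Covariates are centred at fit-time weighted means and
the centring constants serialised, so risks reproduce bit-exactly from
the model files.  The baseline cumulative hazard is the weighted Breslow
estimator with the Efron tie correction; how absolute risks arise from a
weighted interval fit is under-determined in the literature this design
follows, and Breslow-on-weighted-rows is this package's documented
choice.  Robust (sandwich) covariance clusters score residuals
(Breslow-form approximation) by subject and is reported for all weighted
fits.  Kaplan–Meier (with Greenwood-based CIs) and Nelson–Aalen come from
lifelines; the fitter itself is cross-checked against
`lifelines.CoxTimeVaryingFitter` and an exhaustive grid-search oracle in
the tests.

Fractional polynomials use the standard power set
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} with repeated-pair convention
`(v^p, v^p log v)`, automatic shift-to-positivity and power-of-ten
scaling (anchored on a variable's full simulated range so frozen
transforms remain valid on validation and drifted values; calendar time
is shifted by one year).  Selection is the closed test at α = 0.05: best
FP2 vs null (4 df), vs linear (3 df), vs best FP1 (2 df).  Specs selected
on the development fit are frozen and reused in the MSM and weight
models; selection is never run on weighted data.

Decile calibration groups subjects by ranked predicted risk (stable
ties), compares group-mean predicted risk with the group Kaplan–Meier
risk at 5 years, and flags agreement by the Greenwood 95% CI.  With all
predictions equal the stable ranking yields near-equal groups.

## Scenario presets and problem sizes

Shipped scenarios are calibrated so each property is testable at
single-CPU Monte-Carlo precision (n = 20k–50k subjects; event rates an
order of magnitude above real CVD incidence, since decile calibration at
1–2% five-year risk would need the millions of subjects the original
cohorts have):

- `default` — trend −0.05/yr, initiation 1.5%/yr rising at +0.08/yr,
  statin HR 0.75, reference event hazard 0.02/yr, QRISK-flavoured
  covariates, subject-level MCAR on SBP (30%) and sporadic MCAR on
  smoking (10%).
- `confounded` — no trend; a drifting risk factor (drift 0.5/step) with
  outcome log HR 0.25 and initiation log HR 0.8, initiation 0.2/yr,
  reference hazard 0.07/yr: strong time-varying confounding (baseline-
  only adjustment errs by ≈ +0.14 on `βA`) that the MSM corrects.
- `drop_in_only` — calendar time affects events only through rising
  initiation; the MSM's direct calendar coefficient is null.
- `null_trend` — no trend, no drop-in: calibration control (here the
  MSM family degenerates, by construction, to the unweighted interval
  Cox model).
- `trend_recovery` — event-rich (reference hazard 0.08/yr), treatment-
  free design giving ≈ 6,800 development events, sized so the
  calendar-coefficient standard error (≈ 0.004) supports a 15% recovery
  check on γT = −0.05.

The causal-recovery check averages estimates over three replicate
simulations: a single draw has Monte-Carlo standard error ≈ 0.03 on
`βA`, comparable to the 0.05 recovery band, and the property under test
is the estimator's central tendency.  A small residual gap (≈ +0.02)
between the MSM estimate and the conditional log 0.75 is expected: the
MSM marginalises over covariate drift, and the marginal hazard ratio is
attenuated relative to the conditional one (non-collapsibility).

## Known limitations

- Treatment is a single absorbing initiation; discontinuation and
  re-initiation are out of scope.
- No treatment–covariate interactions in the MSM (`A_t·X0` terms).
- Weight models share the outcome model's covariates (first-order FP
  reduction); no automated weight-model selection.
- The robust variance uses Breslow-form score residuals even under Efron
  ties (exact only without ties; simulated event times are continuous,
  so ties are essentially absent).
- Decile Kaplan–Meier risks at the 5-year horizon are mildly tilted when
  entry date drives both risk (through the trend) and administrative
  censoring; the Greenwood bands absorb this at the shipped sizes.
- Categorical covariates are imputed from their marginal distribution in
  the chained-equations stage.
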