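# sectrend

Secular-trend miscalibration in survival risk prediction, with marginal
structural Cox models for treatment drop-in.

## The problem

Clinical 5-year risk scores (QRISK-style cardiovascular models) are
developed on electronic-health-record cohorts spanning 15+ calendar years.
If event incidence declines over that window — a *secular trend* — a model
that ignores calendar time will over-predict risk for present-day patients.
Part of such a trend may be an artefact of *treatment drop-in*: patients
untreated at baseline who start statins during follow-up, lowering observed
event rates without any change in underlying risk.  Deciding whether to
model the trend requires separating these two mechanisms, because building
the drop-in effect into lower risk predictions would talk the very patients
who benefit from treatment out of receiving it.

`sectrend` implements that assessment as a tested pipeline on synthetic
cohorts with known ground truth:

1. **Simulate** a primary-prevention cohort: entries uniform over a
   calendar window, mixed-type covariates drifting at 6-month steps, a
   piecewise-exponential event process with a calendar trend in the log
   hazard, confounded statin initiation (hazard depending on *current*
   covariates and calendar time), a protective causal statin effect, random
   and 5-year administrative censoring, and realistic missingness.
2. **Quantify the miscalibration**: split at a calendar cut date
   (development / validation), fit a Cox model
   `h(t) = h0(t) exp(βX·X0)` with fractional-polynomial selection for
   continuous predictors, and compare decile-mean predicted 5-year risks
   with Kaplan–Meier observed risks.
3. **Model the trend**: refit with calendar time at entry,
   `h(t) = h0(t) exp(βT·T0 + βX·X0)`, and re-assess validation calibration.
4. **Separate trend from drop-in** with a marginal structural model (MSM):
   derive counting-process data at ten 6-month time points, estimate
   stabilised inverse-probability-of-treatment weights

   `sw_i = Π_k (p*_k)^{A_k} (1−p*_k)^{1−A_k} / Π_k (p_k)^{A_k} (1−p_k)^{1−A_k}`

   from interval-censored Cox initiation models (numerator: baseline
   covariates; denominator: baseline + time-varying covariates), and fit
   weighted Cox models `h(t) = h0(t) exp(βA·A_t + βX·X0 [+ βT·T0])`.
   Counterfactual never-treated risks `E[Y(Ā=0)|X0]` then yield the
   relative reduction in mean validation risk attributable to the trend
   after accounting for statin use during follow-up.

The weighted counting-process Cox engine (Efron ties, Newton–Raphson with
step-halving, weighted Breslow baseline hazard, cluster-robust sandwich
covariance) is implemented in-package and cross-checked against lifelines
in the test suite.

## Worked example

```python
import sectrend as st

scenario, study = st.builtin_scenario("default", n_subjects=50_000)
report = st.run_study(scenario, study, seed=1, outdir="out")
print(report.risk_ratios[["model_family", "mean_risk_unadjusted_pct",
                          "mean_risk_adjusted_pct",
                          "relative_reduction_pct"]].round(2).to_string(index=False))
```

prints

```
model_family  mean_risk_unadjusted_pct  mean_risk_adjusted_pct  relative_reduction_pct
interval_cox                      7.73                    4.37                   43.42
         msm                      7.95                    4.55                   42.74
```

Reading: the model without calendar time predicts a mean 5-year risk of
7.7% for validation subjects; adding calendar time drops it to 4.4% — a
43% relative reduction.  Under the MSM, which removes the influence of
statin initiation during follow-up, the reduction is almost as large
(43%), so in this scenario the secular trend is *not* explained by rising
statin use — the same qualitative conclusion the analysis is designed to
reach, here verifiable because the generator's direct trend
(−0.05/yr on the log hazard) is known.  `out/` additionally receives
decile calibration tables and figures (development, validation without and
with calendar time), the MSM coefficient table with robust SEs, weight
diagnostics, serialised models, and a run log.

The same pipeline is scriptable from the shell:

```bash
sectrend run-all --preset default --seed 1 --outdir out
sectrend simulate --config scenarios/confounded.yaml --outdir out   # stages
```

Scenario YAML files (`scenarios/`) expose every generator parameter;
`builtin_scenario` provides the calibrated presets (`default`,
`confounded`, `drop_in_only`, `null_trend`, `trend_recovery`).

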