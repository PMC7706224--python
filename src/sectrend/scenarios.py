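"""Built-in scenario presets.

Each preset fixes the data-generating conditions of one study design:

``default``
    The headline scenario: a 1998–2015 window, a downward calendar trend
    in the event hazard (-0.05/yr on the log scale), statin drop-in at
    1.5%/yr rising over calendar time, a protective causal statin effect
    (HR 0.75), QRISK-flavoured covariates (age, SBP, smoking, diabetes)
    that also drive initiation, and MCAR missingness on SBP and smoking.
``confounded``
    Strong time-varying confounding: a drifting risk factor steers both
    initiation and the outcome, initiation is frequent, events are common
    enough for a precise causal estimate.  Built to make the baseline-only
    adjusted estimate visibly biased while the weighted MSM recovers the
    true effect.
``drop_in_only``
    Calendar time affects events *only* through rising statin initiation
    (no direct outcome trend): the MSM's calendar coefficient should be
    null.
``null_trend``
    No secular trend and no drop-in: a calibration control.
``trend_recovery``
    Event-rich, treatment-free design for precise estimation of the
    calendar-time coefficient itself.

Sizes are chosen so the estimator checks run at conventional Monte-Carlo
precision on a single CPU; ``n_subjects`` can be overridden.
"""

from __future__ import annotations

from .config import CovariateSpec, MissingSpec, ScenarioConfig, StudyConfig

HR_STATIN = 0.75        # causal statin hazard ratio on events
LOG_HR_STATIN = -0.2876820724517809  # log(0.75)


def _qrisk_style_covariates():
    return [
        CovariateSpec("age", "continuous", mean=45.0, sd=12.0,
                      outcome_log_hr=0.05, initiation_log_hr=0.06,
                      drift_sd=0.25),
        CovariateSpec("sbp", "continuous", mean=128.0, sd=16.0,
                      outcome_log_hr=0.012, initiation_log_hr=0.02,
                      drift_sd=4.0),
        CovariateSpec("smoker", "binary", p=0.30,
                      outcome_log_hr=0.45, initiation_log_hr=0.30),
        CovariateSpec("diabetes", "binary", p=0.06,
                      outcome_log_hr=0.60, initiation_log_hr=0.80),
    ]


def builtin_scenario(name: str, n_subjects: int | None = None,
                     seed: int | None = None) -> tuple[ScenarioConfig, StudyConfig]:
    """Return ``(ScenarioConfig, StudyConfig)`` for a named preset."""
    if name == "default":
        scenario = ScenarioConfig(
            n_subjects=20_000 if n_subjects is None else n_subjects,
            calendar_window=("1998-01-01", "2015-12-31"),
            covariates=_qrisk_style_covariates(),
            baseline_event_hazard=0.020,
            trend_outcome=-0.05,
            baseline_initiation_hazard=0.015,
            trend_initiation=0.08,
            treatment_log_hr=LOG_HR_STATIN,
            random_censor_hazard=0.02,
            missingness={"sbp": MissingSpec(0.30, "mcar", level="subject"),
                         "smoker": MissingSpec(0.10, "mcar")},
            seed=0 if seed is None else seed,
        )
        study = StudyConfig(cut_date="2010-01-01", fp_variables=("age", "sbp"))
        return scenario, study

    if name == "confounded":
        scenario = ScenarioConfig(
            n_subjects=50_000 if n_subjects is None else n_subjects,
            calendar_window=("1998-01-01", "2015-12-31"),
            covariates=[
                CovariateSpec("risk_score", "continuous", mean=0.0, sd=1.0,
                              outcome_log_hr=0.25, initiation_log_hr=0.80,
                              drift_sd=0.50),
                CovariateSpec("smoker", "binary", p=0.30,
                              outcome_log_hr=0.40, initiation_log_hr=0.30),
            ],
            baseline_event_hazard=0.070,
            trend_outcome=0.0,
            baseline_initiation_hazard=0.20,
            trend_initiation=0.0,
            treatment_log_hr=LOG_HR_STATIN,
            random_censor_hazard=0.01,
            seed=0 if seed is None else seed,
        )
        study = StudyConfig(cut_date="2011-01-01", fp_variables=())
        return scenario, study

    if name == "drop_in_only":
        scenario = ScenarioConfig(
            n_subjects=20_000 if n_subjects is None else n_subjects,
            calendar_window=("1998-01-01", "2015-12-31"),
            covariates=[
                CovariateSpec("risk_score", "continuous", mean=0.0, sd=1.0,
                              outcome_log_hr=0.30, initiation_log_hr=0.40,
                              drift_sd=0.40),
            ],
            baseline_event_hazard=0.050,
            trend_outcome=0.0,          # no direct secular trend …
            baseline_initiation_hazard=0.10,
            trend_initiation=0.10,      # … only rising statin uptake
            treatment_log_hr=LOG_HR_STATIN,
            random_censor_hazard=0.01,
            seed=0 if seed is None else seed,
        )
        study = StudyConfig(cut_date="2010-01-01", fp_variables=())
        return scenario, study

    if name == "null_trend":
        scenario = ScenarioConfig(
            n_subjects=20_000 if n_subjects is None else n_subjects,
            calendar_window=("1998-01-01", "2015-12-31"),
            covariates=_qrisk_style_covariates(),
            baseline_event_hazard=0.010,
            trend_outcome=0.0,
            baseline_initiation_hazard=0.0,
            trend_initiation=0.0,
            treatment_log_hr=0.0,
            random_censor_hazard=0.02,
            missingness={},
            seed=0 if seed is None else seed,
        )
        study = StudyConfig(cut_date="2010-01-01", fp_variables=("age", "sbp"))
        return scenario, study

    if name == "trend_recovery":
        scenario = ScenarioConfig(
            n_subjects=50_000 if n_subjects is None else n_subjects,
            calendar_window=("1998-01-01", "2015-12-31"),
            covariates=[
                CovariateSpec("age", "continuous", mean=45.0, sd=12.0,
                              outcome_log_hr=0.03, drift_sd=0.25),
                CovariateSpec("smoker", "binary", p=0.30, outcome_log_hr=0.40),
            ],
            baseline_event_hazard=0.080,
            trend_outcome=-0.05,
            baseline_initiation_hazard=0.0,   # treatment-free by design
            trend_initiation=0.0,
            treatment_log_hr=0.0,
            random_censor_hazard=0.01,
            seed=0 if seed is None else seed,
        )
        study = StudyConfig(cut_date="2010-01-01", fp_variables=())
        return scenario, study

    raise KeyError(f"unknown scenario preset {name!r}")
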