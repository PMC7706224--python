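scenario:
  n_subjects: 20000
  calendar_window:
  - '1998-01-01'
  - '2015-12-31'
  covariates:
  - name: risk_score
    kind: continuous
    mean: 0.0
    sd: 1.0
    p: 0.5
    levels: []
    probs: []
    outcome_log_hr: 0.3
    initiation_log_hr: 0.4
    drift_sd: 0.4
    reference: null
  baseline_event_hazard: 0.05
  trend_outcome: 0.0
  baseline_initiation_hazard: 0.1
  trend_initiation: 0.1
  treatment_log_hr: -0.2876820724517809
  random_censor_hazard: 0.01
  admin_horizon: 5.0
  missingness: {}
  seed: 0
study:
  cut_date: '2010-01-01'
  fp_variables: []
  calendar_fp: true
  n_groups: 10
  fp_alpha: 0.05
  weight_truncation: null
  weight_model_full_fp: false
  horizon: 5.0
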