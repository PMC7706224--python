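scenario:
  n_subjects: 20000
  calendar_window:
  - '1998-01-01'
  - '2015-12-31'
  covariates:
  - name: age
    kind: continuous
    mean: 45.0
    sd: 12.0
    p: 0.5
    levels: []
    probs: []
    outcome_log_hr: 0.05
    initiation_log_hr: 0.06
    drift_sd: 0.25
    reference: null
  - name: sbp
    kind: continuous
    mean: 128.0
    sd: 16.0
    p: 0.5
    levels: []
    probs: []
    outcome_log_hr: 0.012
    initiation_log_hr: 0.02
    drift_sd: 4.0
    reference: null
  - name: smoker
    kind: binary
    mean: 0.0
    sd: 1.0
    p: 0.3
    levels: []
    probs: []
    outcome_log_hr: 0.45
    initiation_log_hr: 0.3
    drift_sd: 0.0
    reference: null
  - name: diabetes
    kind: binary
    mean: 0.0
    sd: 1.0
    p: 0.06
    levels: []
    probs: []
    outcome_log_hr: 0.6
    initiation_log_hr: 0.8
    drift_sd: 0.0
    reference: null
  baseline_event_hazard: 0.01
  trend_outcome: 0.0
  baseline_initiation_hazard: 0.0
  trend_initiation: 0.0
  treatment_log_hr: 0.0
  random_censor_hazard: 0.02
  admin_horizon: 5.0
  missingness: {}
  seed: 0
study:
  cut_date: '2010-01-01'
  fp_variables:
  - age
  - sbp
  calendar_fp: true
  n_groups: 10
  fp_alpha: 0.05
  weight_truncation: null
  weight_model_full_fp: false
  horizon: 5.0
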