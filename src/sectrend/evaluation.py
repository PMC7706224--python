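"""Calibration assessment, secular-trend risk ratios, and the study driver.

`run_study` executes the full analysis sequence on one scenario:

1.  simulate the cohort and its missingness;
2.  derive the eligible baseline cohort; impute (LOCF -> NOCB -> one
    stochastic chained-equations imputation at baseline);
3.  split development / validation at the calendar cut date;
4.  fit the baseline-covariate Cox risk model with fractional-polynomial
    selection, and assess decile calibration in both cohorts;
5.  refit with calendar time at entry as a predictor and re-assess
    validation calibration;
6.  build the 6-month counting-process table, estimate stabilised IPT
    weights for statin drop-in, fit marginal structural Cox models with
    and without calendar time plus their unweighted comparators;
7.  report the relative reduction in mean predicted validation risk caused
    by modelling the secular trend, under both frameworks, together with
    MSM coefficient and weight-diagnostic tables.

Everything is seeded; the same configuration and seed reproduce identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cb
from . import impute as imp
from . import msm as msm_mod
from .config import ScenarioConfig, StudyConfig, stage_rng
from .fracpoly import FPSpec, select_fp
from .simulate import Cohort, apply_missingness, simulate_cohort
from .survival import (CoxFit, breslow_baseline, fit_cox, kaplan_meier,
                       nelson_aalen, predict_risk)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# calibration

def calibration_by_group(predicted: np.ndarray, times: np.ndarray,
                         events: np.ndarray, n_groups: int = 10,
                         horizon: float = 5.0) -> pd.DataFrame:
    """Observed (Kaplan–Meier) vs mean predicted risk within risk groups.

    Subjects are ranked by predicted risk (ties broken by stable input
    order) and cut into ``n_groups`` near-equal groups; per group the
    Kaplan–Meier risk at ``horizon`` with its Greenwood-based 95% CI is
    set against the mean predicted risk.
    """
    predicted = np.asarray(predicted, dtype=float)
    n = len(predicted)
    if n_groups < 1 or n_groups > n:
        raise ValueError(f"n_groups must be in [1, {n}]")
    order = np.argsort(predicted, kind="stable")
    rows = []
    for g, idx in enumerate(np.array_split(order, n_groups)):
        km = kaplan_meier(np.asarray(times)[idx], np.asarray(events)[idx])
        t_eval = min(horizon, float(np.max(np.asarray(times)[idx])))
        lo, hi = km.risk_ci_at(t_eval)
        rows.append({
            "group": g + 1,
            "n": len(idx),
            "mean_predicted": float(predicted[idx].mean()),
            "km_observed": float(km.risk_at(t_eval)),
            "ci_low": float(lo),
            "ci_high": float(hi),
        })
    return pd.DataFrame(rows)


@dataclass
class RiskRatioReport:
    """Mean predicted validation risk before/after modelling calendar time."""

    cohort_label: str
    model_family: str               # "interval_cox" | "msm"
    mean_risk_unadjusted: float
    mean_risk_adjusted: float

    @property
    def relative_reduction_pct(self) -> float:
        if self.mean_risk_unadjusted == 0:
            return 0.0
        return 100.0 * (self.mean_risk_unadjusted - self.mean_risk_adjusted) \
            / self.mean_risk_unadjusted

    def as_row(self) -> dict:
        return {
            "cohort": self.cohort_label,
            "model_family": self.model_family,
            "mean_risk_unadjusted_pct": 100 * self.mean_risk_unadjusted,
            "mean_risk_adjusted_pct": 100 * self.mean_risk_adjusted,
            "relative_reduction_pct": self.relative_reduction_pct,
        }


def secular_trend_risk_ratio(risks_unadjusted: np.ndarray,
                             risks_adjusted: np.ndarray,
                             cohort_label: str = "validation",
                             model_family: str = "interval_cox") -> RiskRatioReport:
    """Relative reduction in the mean predicted risk of a cohort when
    calendar time is added to the model."""
    ru = np.asarray(risks_unadjusted, dtype=float)
    ra = np.asarray(risks_adjusted, dtype=float)
    if len(ru) == 0 or len(ra) == 0:
        raise ValueError("empty cohort: no risks to average")
    return RiskRatioReport(cohort_label, model_family,
                           float(ru.mean()), float(ra.mean()))


# ---------------------------------------------------------------------------
# design-matrix helpers

def apply_fp_design(df: pd.DataFrame, specs: dict, linear: list,
                    prefix: str = "x0_") -> tuple[pd.DataFrame, list]:
    """Expand a covariate table into FP-transformed design columns.

    ``specs`` maps variable name -> frozen FPSpec (a spec with empty
    powers drops the variable); ``linear`` lists variables entering
    untransformed.  Returns the augmented frame and design column names.
    """
    out = df.copy()
    names = []
    for var, spec in specs.items():
        basis = spec.transform(df[prefix + var].to_numpy(dtype=float))
        for j, cname in enumerate(spec.column_names()):
            col = f"{prefix}{cname}"
            out[col] = basis[:, j]
            names.append(col)
    for var in linear:
        names.append(prefix + var)
    return out, names


def reduce_specs_for_weights(specs: dict, full_fp: bool) -> dict:
    """Weight-model parsimony: keep only first-order FP terms by default."""
    if full_fp:
        return dict(specs)
    out = {}
    for var, spec in specs.items():
        powers = spec.powers[:1] if spec.powers else (1.0,)
        out[var] = FPSpec(spec.name, tuple(powers), spec.shift, spec.scale)
    return out


# ---------------------------------------------------------------------------
# study driver

@dataclass
class StudyReport:
    calibration_development: pd.DataFrame
    calibration_validation: pd.DataFrame
    calibration_validation_trend: pd.DataFrame
    risk_ratios: pd.DataFrame
    msm_coefficients: pd.DataFrame
    weight_diagnostics: dict
    fp_specs: dict
    models: dict = field(repr=False)
    counts: dict = field(default_factory=dict)
    missingness: pd.DataFrame | None = None

    def write(self, outdir, make_figures: bool = True) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.calibration_development.to_csv(
            outdir / "calibration_development.csv", index=False)
        self.calibration_validation.to_csv(
            outdir / "calibration_validation.csv", index=False)
        self.calibration_validation_trend.to_csv(
            outdir / "calibration_validation_trend.csv", index=False)
        self.risk_ratios.to_csv(outdir / "risk_ratio.csv", index=False)
        self.msm_coefficients.to_csv(outdir / "msm_coefficients.csv", index=False)
        if self.missingness is not None:
            self.missingness.to_csv(outdir / "missingness_report.csv",
                                    index=False)
        with open(outdir / "models.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in self.models.items()}, fh,
                      indent=1)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump({
                "weight_diagnostics": self.weight_diagnostics,
                "fp_specs": {k: dataclasses.asdict(v)
                             for k, v in self.fp_specs.items()},
                "counts": self.counts,
            }, fh, indent=1, default=str)
        if make_figures:
            self._figures(outdir)

    def _figures(self, outdir: Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        panels = [
            ("calibration_development", self.calibration_development,
             "Development cohort"),
            ("calibration_validation", self.calibration_validation,
             "Validation cohort (no calendar time)"),
            ("calibration_validation_trend", self.calibration_validation_trend,
             "Validation cohort (calendar time modelled)"),
        ]
        fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharex=False)
        for ax, (_, tab, title) in zip(axes, panels):
            ax.errorbar(tab["mean_predicted"], tab["km_observed"],
                        yerr=[tab["km_observed"] - tab["ci_low"],
                              tab["ci_high"] - tab["km_observed"]],
                        fmt="o", capsize=3)
            lim = max(tab["mean_predicted"].max(), tab["ci_high"].max()) * 1.1
            ax.plot([0, lim], [0, lim], "k--", lw=0.8)
            ax.set_xlabel("mean predicted 5-year risk")
            ax.set_ylabel("KM observed 5-year risk")
            ax.set_title(title, fontsize=9)
        fig.tight_layout()
        fig.savefig(outdir / "fig_calibration.png", dpi=120)
        plt.close(fig)


def run_study(scenario: ScenarioConfig, study: StudyConfig,
              seed: int | None = None, outdir=None,
              make_figures: bool = True) -> StudyReport:
    """Execute the full secular-trend / drop-in analysis on one scenario."""
    study.validate(scenario)
    seed = scenario.seed if seed is None else int(seed)
    horizon = study.horizon
    cut = scenario.date_to_years(study.cut_date)
    counts = {}

    # 1-2. simulate, mask, derive, impute
    cohort = simulate_cohort(scenario, seed=seed)
    apply_missingness(cohort, seed=seed)
    baseline, filled = prepare_baseline(cohort, seed=seed)
    counts["n_simulated"] = cohort.n
    counts["n_baseline"] = len(baseline)

    # missingness report (per-variable observed fractions)
    miss_rows = [{"variable": name,
                  "missing_baseline_pct": 100 * float(cohort.mask[name][:, 0].mean()),
                  "missing_any_timepoint_pct":
                      100 * float(cohort.mask[name].any(axis=1).mean()),
                  "missing_all_timepoints_pct":
                      100 * float(cohort.mask[name].all(axis=1).mean())}
                 for name in cohort.values]
    missingness = pd.DataFrame(miss_rows)

    # 3. calendar split
    dev, val = cb.split_by_cut_date(baseline, cut, scenario.window_years)
    counts["n_development"], counts["n_validation"] = len(dev), len(val)
    if len(val) == 0:
        raise ValueError("empty validation cohort")

    kinds = {c.name: c.kind for c in scenario.covariates}
    continuous = [v for v in study.fp_variables if kinds.get(v) == "continuous"]
    linear = [c.name for c in scenario.covariates if c.name not in continuous]

    # 4. baseline-covariate risk model with FP selection
    # shift/scale anchored on the variable's full simulated range so the
    # frozen transforms stay positive on validation and drifted values
    from .fracpoly import auto_shift_scale
    ranges = {var: auto_shift_scale(filled[var][np.isfinite(filled[var])])
              for var in continuous}
    specs: dict[str, FPSpec] = {}
    for var in continuous:
        work, adj = apply_fp_design(dev, specs, linear)
        specs[var] = _select_fp_baseline(work, var, adj, study.fp_alpha,
                                         *ranges[var])
    dev_d, design = apply_fp_design(dev, specs, linear)
    val_d, _ = apply_fp_design(val, specs, linear)
    dev_d["_zero"] = 0.0
    fit_plain = fit_cox(dev_d, design, start="_zero", stop="follow",
                        event="event", id_col="id")
    risk_dev = predict_risk(fit_plain, dev_d[design], horizon)
    risk_val = predict_risk(fit_plain, val_d[design], horizon)
    cal_dev = calibration_by_group(risk_dev, dev["follow"], dev["event"],
                                   study.n_groups, horizon)
    cal_val = calibration_by_group(risk_val, val["follow"], val["event"],
                                   study.n_groups, horizon)

    # 5. calendar-time model
    if study.calendar_fp:
        # calendar time starts at ~0; shift by one year so negative powers
        # stay bounded over the whole window
        specs["t0"] = _select_fp_baseline(dev_d, "t0", design, study.fp_alpha,
                                          shift=1.0, scale=10.0)
        if not specs["t0"].powers:  # keep calendar time in the trend model
            specs["t0"] = FPSpec("t0", (1.0,), specs["t0"].shift,
                                 specs["t0"].scale)
    else:
        from .fracpoly import auto_shift_scale
        sh, sc = auto_shift_scale(dev["t0"].to_numpy())
        specs["t0"] = FPSpec("t0", (1.0,), sh, sc)
    t0_spec = specs["t0"]

    def add_t0(frame):
        basis = t0_spec.transform(frame["t0"].to_numpy(dtype=float))
        cols = [f"x0_{c}" for c in t0_spec.column_names()]
        for j, c in enumerate(cols):
            frame[c] = basis[:, j]
        return cols

    t0_cols = add_t0(dev_d)
    add_t0(val_d)
    design_t = design + t0_cols
    fit_trend = fit_cox(dev_d, design_t, start="_zero", stop="follow",
                        event="event", id_col="id")
    risk_val_t = predict_risk(fit_trend, val_d[design_t], horizon)
    cal_val_t = calibration_by_group(risk_val_t, val["follow"], val["event"],
                                     study.n_groups, horizon)

    # 6. counting-process table, weights, MSMs
    init_times = cb.effective_initiation(cohort, dev)
    intervals = cb.build_interval_table(dev, cohort, filled, init_times)
    xspecs = {v: s for v, s in specs.items() if v != "t0"}
    intervals, xk_design, x0_design = _interval_design(intervals, xspecs,
                                                       linear, continuous)
    t0i_cols = _interval_t0(intervals, t0_spec)

    wspecs = reduce_specs_for_weights(xspecs, study.weight_model_full_fp)
    intervals, wk_design, w0_design = _interval_design(intervals, wspecs,
                                                       linear, continuous,
                                                       suffix="_w")
    init_table = msm_mod.build_initiation_table(intervals, init_times)
    any_drop_in = bool(init_table["init_event"].sum())

    def weights_for(include_t0: bool):
        denom = wk_design + w0_design + (t0i_cols if include_t0 else [])
        numer = w0_design + (t0i_cols if include_t0 else [])
        den_fit, num_fit = msm_mod.fit_initiation_models(init_table, denom, numer)
        p_den = msm_mod.interval_probabilities(den_fit, init_table)
        p_num = msm_mod.interval_probabilities(num_fit, init_table)
        return msm_mod.compute_stabilised_weights(
            intervals, init_table, p_num, p_den, study.weight_truncation)

    if any_drop_in:
        ws_plain = weights_for(False)
        ws_trend = weights_for(True)
        msm_plain = msm_mod.fit_msm(intervals, x0_design, ws_plain)
        msm_trend = msm_mod.fit_msm(intervals, x0_design + t0i_cols, ws_trend)
    else:
        # no treatment drop-in anywhere: all weights are 1 and the
        # marginal structural model collapses onto the interval Cox model
        log.info("no statin initiations in the development cohort; "
                 "MSM family reduces to the unweighted interval Cox model")
        unit = np.ones(len(intervals))
        ws_plain = ws_trend = msm_mod.WeightSet(
            table_index=intervals.index.to_numpy(), sw=unit,
            p_num=np.full(len(intervals), np.nan),
            p_den=np.full(len(intervals), np.nan), factor=unit)
        msm_plain = fit_cox(intervals, x0_design, start="start", stop="stop",
                            event="event", id_col="id", robust=True)
        msm_trend = fit_cox(intervals, x0_design + t0i_cols, start="start",
                            stop="stop", event="event", id_col="id",
                            robust=True)
    icox_plain = fit_cox(intervals, x0_design, start="start", stop="stop",
                         event="event", id_col="id", robust=True)
    icox_trend = fit_cox(intervals, x0_design + t0i_cols, start="start",
                         stop="stop", event="event", id_col="id", robust=True)

    # 7. validation risk ratios (Table-3 analogue) and coefficients (Table-4)
    val_i = val_d  # already carries every x0_/t0 design column by construction
    rr_icox = secular_trend_risk_ratio(
        predict_risk(icox_plain, val_i[x0_design], horizon),
        predict_risk(icox_trend, val_i[x0_design + t0i_cols], horizon),
        model_family="interval_cox")
    val_msm = val_i.copy()
    val_msm["treat"] = 0.0
    rr_msm = secular_trend_risk_ratio(
        msm_mod.counterfactual_risk(msm_plain, val_msm[["treat"] + x0_design],
                                    horizon),
        msm_mod.counterfactual_risk(msm_trend,
                                    val_msm[["treat"] + x0_design + t0i_cols],
                                    horizon),
        model_family="msm")
    risk_ratios = pd.DataFrame([rr_icox.as_row(), rr_msm.as_row()])

    coef_rows = []
    for label, fit in (("msm_no_trend", msm_plain), ("msm_trend", msm_trend)):
        se = fit.se(robust=True)
        for name, b, s in zip(fit.names, fit.coef, se):
            coef_rows.append({"model": label, "variable": name,
                              "log_hr": b, "se": s})
    msm_coefs = pd.DataFrame(coef_rows)

    report = StudyReport(
        calibration_development=cal_dev,
        calibration_validation=cal_val,
        calibration_validation_trend=cal_val_t,
        risk_ratios=risk_ratios,
        msm_coefficients=msm_coefs,
        weight_diagnostics={"no_trend": ws_plain.diagnostics(),
                            "trend": ws_trend.diagnostics()},
        fp_specs=specs,
        models={"cox_plain": fit_plain, "cox_trend": fit_trend,
                "msm_no_trend": msm_plain, "msm_trend": msm_trend,
                "interval_cox_no_trend": icox_plain,
                "interval_cox_trend": icox_trend},
        counts=counts,
        missingness=missingness,
    )
    if outdir is not None:
        report.write(outdir, make_figures=make_figures)
    return report


# ---------------------------------------------------------------------------
# pipeline helpers

def prepare_baseline(cohort: Cohort, seed: int,
                     study_end_years: float | None = None) -> tuple:
    """LOCF/NOCB, Nelson–Aalen auxiliary, stochastic baseline imputation.

    Returns the completed baseline table and fully imputed covariate paths
    (imputed baseline values carried forward to later time points).
    """
    end = cohort.config.window_years if study_end_years is None else study_end_years
    filled, residual = imp.locf_then_nocb(cohort.values, cohort.mask)
    baseline = cb.derive_baseline_cohort(cohort, end, values=filled)
    na_exit, _ = nelson_aalen(baseline["follow"], baseline["event"])
    baseline["na_hazard"] = na_exit
    kinds = {c.name: c.kind for c in cohort.config.covariates}
    imp_seed = stage_rng(seed, 2).integers(2**31)
    baseline = imp.stochastic_baseline_imputation(baseline, kinds,
                                                  seed=int(imp_seed))
    filled = imp.carry_baseline_forward(filled, residual, baseline, cohort.ids)
    return baseline, filled


def _select_fp_baseline(dev: pd.DataFrame, var: str, adjust: list,
                        alpha: float, shift: float | None = None,
                        scale: float | None = None) -> FPSpec:
    work = dev.copy()
    work["_zero"] = 0.0
    src = f"x0_{var}" if f"x0_{var}" in work.columns else var
    work["_x"] = work[src]
    spec = select_fp(work, "_x", adjust=adjust, start="_zero", stop="follow",
                     event="event", alpha=alpha, shift=shift, scale=scale)
    return FPSpec(var, spec.powers, spec.shift, spec.scale)


def _interval_design(intervals: pd.DataFrame, specs: dict, linear: list,
                     continuous: list, suffix: str = "") -> tuple:
    """FP-transform both the time-varying (xk_) and baseline (x0_) columns."""
    xk_names, x0_names = [], []
    for var, spec in specs.items():
        if not spec.powers:
            continue
        for src_prefix, sink in (("xk_", xk_names), ("x0_", x0_names)):
            basis = spec.transform(intervals[src_prefix + var].to_numpy(float))
            for j, cname in enumerate(spec.column_names()):
                col = f"{src_prefix}{cname}{suffix}"
                intervals[col] = basis[:, j]
                sink.append(col)
    for var in linear:
        xk_names.append(f"xk_{var}")
        x0_names.append(f"x0_{var}")
    return intervals, xk_names, x0_names


def _interval_t0(intervals: pd.DataFrame, t0_spec: FPSpec) -> list:
    basis = t0_spec.transform(intervals["t0_years"].to_numpy(float))
    cols = []
    for j, cname in enumerate(t0_spec.column_names()):
        col = f"x0_{cname}"
        intervals[col] = basis[:, j]
        cols.append(col)
    return cols
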