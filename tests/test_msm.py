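"""Stabilised IPT weights and marginal structural Cox fits."""

import numpy as np
import pandas as pd
import pytest

from sectrend import builtin_scenario, simulate_cohort
from sectrend.cohort import (build_interval_table, derive_baseline_cohort,
                             effective_initiation)
from sectrend.msm import (PositivityError, WeightSet, build_initiation_table,
                          compute_stabilised_weights, fit_initiation_models,
                          fit_msm, interval_probabilities)
from sectrend.survival import CoxFit, StepFunction, fit_cox


def toy_intervals(n_int, init_k=None):
    """One subject with n_int half-year intervals, optional initiation in
    interval ``init_k`` (treated from the following interval on)."""
    k = np.arange(n_int)
    init = np.nan if init_k is None else (init_k + 0.25) * 0.5 + init_k * 0.0
    init = np.nan if init_k is None else init_k * 0.5 + 0.25
    treat = np.zeros(n_int, dtype=int) if init_k is None else \
        (k * 0.5 > init).astype(int)
    tab = pd.DataFrame({"id": 1, "k": k, "start": k * 0.5,
                        "stop": (k + 1) * 0.5, "event": 0, "treat": treat,
                        "t0_years": 0.0})
    return tab, pd.Series([init], index=[1])


class TestWeightArithmetic:
    def test_identity_when_numerator_equals_denominator(self):
        tab, init = toy_intervals(4)
        it = build_initiation_table(tab, init)
        p = np.array([0.1, 0.2, 0.05, 0.15])
        ws = compute_stabilised_weights(tab, it, p, p)
        np.testing.assert_allclose(ws.sw, 1.0)

    def test_never_treated_product(self):
        """After surviving two untreated transitions with p*=0.1, p=0.2 the
        carried weight is (0.9/0.8)^2 = 1.2656 (direct product)."""
        tab, init = toy_intervals(3)
        it = build_initiation_table(tab, init)
        ws = compute_stabilised_weights(tab, it, np.array([0.1] * 3),
                                        np.array([0.2] * 3))
        np.testing.assert_allclose(
            ws.sw, [1.0, 0.9 / 0.8, (0.9 / 0.8) ** 2], atol=1e-12)
        assert ws.sw[-1] == pytest.approx(1.2656, abs=2e-4)

    def test_initiation_factor_carried_from_first_treated_row(self):
        """An initiation transition with p*=0.1, p=0.3 (earlier factors
        p*=p) sets sw = 1/3 from the first treated interval onward,
        constant thereafter (treatment is absorbing)."""
        tab, init = toy_intervals(5, init_k=0)
        it = build_initiation_table(tab, init)
        assert list(it["k"]) == [0]
        assert list(it["init_event"]) == [1]
        ws = compute_stabilised_weights(tab, it, np.array([0.1]),
                                        np.array([0.3]))
        np.testing.assert_allclose(ws.sw, [1.0] + [1 / 3] * 4)
        assert ws.sw[1] == pytest.approx(0.3333, abs=2e-4)
        # factors on treated rows are exactly 1
        np.testing.assert_allclose(ws.factor[1:], 1.0)

    def test_positivity_violation_rejected(self):
        tab, init = toy_intervals(2)
        it = build_initiation_table(tab, init)
        with pytest.raises(PositivityError):
            compute_stabilised_weights(tab, it, np.array([0.1, 0.1]),
                                       np.array([0.2, 1.0]))

    def test_truncation_bounds(self):
        rng = np.random.default_rng(0)
        tabs, its, pn, pdn = [], [], [], []
        for i in range(200):
            t, init = toy_intervals(3)
            t["id"] = i
            tabs.append(t)
            its.append(build_initiation_table(t, pd.Series([np.nan], index=[i])))
            pn.append(rng.uniform(0.01, 0.3, 3))
            pdn.append(rng.uniform(0.01, 0.3, 3))
        tab = pd.concat(tabs, ignore_index=True)
        it = pd.concat(its)
        it.index = tab.index[tab["treat"] == 0]
        ws = compute_stabilised_weights(tab, it, np.concatenate(pn),
                                        np.concatenate(pdn),
                                        truncation=(5, 95))
        lo, hi = ws.bounds
        assert np.all(ws.sw >= lo - 1e-12) and np.all(ws.sw <= hi + 1e-12)
        assert ws.n_truncated > 0


class TestIntervalProbabilities:
    def make_fit(self, dh):
        fit = CoxFit(names=["z"], coef=np.array([0.0]),
                     var_model=np.eye(1), means=np.array([0.0]),
                     loglik=0.0, loglik_null=0.0, n=1, n_events=1,
                     ties="efron", converged=True, n_iter=1)
        fit.baseline = StepFunction(np.array([0.25, 0.75]),
                                    np.array([dh, 2 * dh]))
        return fit

    def test_zero_increment_zero_probability(self):
        fit = self.make_fit(0.0)
        rows = pd.DataFrame({"k": [0], "z": [0.0]})
        assert interval_probabilities(fit, rows)[0] == 0.0

    def test_arithmetic(self):
        fit = self.make_fit(0.1)
        rows = pd.DataFrame({"k": [0], "z": [0.0]})
        p = interval_probabilities(fit, rows)[0]
        assert p == pytest.approx(1 - np.exp(-0.1), abs=1e-12)
        assert p == pytest.approx(0.0952, abs=1e-4)

    def test_monotone_in_linear_predictor(self):
        fit = self.make_fit(0.1)
        fit.coef = np.array([1.0])
        rows = pd.DataFrame({"k": [0, 0, 0], "z": [-1.0, 0.0, 1.0]})
        p = interval_probabilities(fit, rows)
        assert np.all(np.diff(p) > 0)


def drop_in_intervals(scenario_name="confounded", n=20_000, seed=10):
    scenario, _ = builtin_scenario(scenario_name, n_subjects=n)
    cohort = simulate_cohort(scenario, seed=seed)
    base = derive_baseline_cohort(cohort, scenario.window_years,
                                  values=cohort.values)
    init = effective_initiation(cohort, base)
    tab = build_interval_table(base, cohort, dict(cohort.values), init)
    return tab, init, scenario


class TestInitiationModels:
    def test_confounded_coefficient_detected(self):
        """The denominator model must see the positive effect of the
        drifting risk factor on initiation (> 2 SE at n = 20k)."""
        tab, init, _ = drop_in_intervals(seed=21)
        it = build_initiation_table(tab, init)
        den, num = fit_initiation_models(
            it, ["xk_risk_score", "xk_smoker", "x0_risk_score", "x0_smoker"],
            ["x0_risk_score", "x0_smoker"])
        j = den.names.index("xk_risk_score")
        assert den.coef[j] > 0
        assert den.coef[j] / den.se()[j] > 2
        # numerator covariates are a subset of denominator information
        assert set(num.names) <= {"x0_risk_score", "x0_smoker", "xk_smoker"}

    def test_null_initiation_coefficients(self):
        """Initiation independent of covariates: every denominator
        coefficient within 2 SE of zero."""
        from sectrend.config import CovariateSpec, ScenarioConfig
        cfg = ScenarioConfig(
            n_subjects=20_000, baseline_event_hazard=0.03,
            baseline_initiation_hazard=0.08,
            covariates=[CovariateSpec("z", "continuous", drift_sd=0.4,
                                      outcome_log_hr=0.3)],
            seed=3)
        cohort = simulate_cohort(cfg)
        base = derive_baseline_cohort(cohort, cfg.window_years,
                                      values=cohort.values)
        init = effective_initiation(cohort, base)
        tab = build_interval_table(base, cohort, dict(cohort.values), init)
        it = build_initiation_table(tab, init)
        den, _ = fit_initiation_models(it, ["xk_z", "x0_z"], ["x0_z"])
        assert np.all(np.abs(den.coef) < 2 * den.se())

    def test_zero_initiations_rejected(self):
        tab, init = toy_intervals(3)
        tab["xk_z"] = [0.1, 0.5, 0.2]
        it = build_initiation_table(tab, init)
        with pytest.raises(Exception, match="initiation"):
            fit_initiation_models(it, ["xk_z"], [])


class TestMsmFit:
    def test_unit_weights_match_unweighted(self):
        tab, init, _ = drop_in_intervals(n=4000, seed=5)
        ws = WeightSet(table_index=tab.index.to_numpy(),
                       sw=np.ones(len(tab)), p_num=np.full(len(tab), np.nan),
                       p_den=np.full(len(tab), np.nan),
                       factor=np.ones(len(tab)))
        covs = ["x0_risk_score", "x0_smoker"]
        f1 = fit_msm(tab, covs, ws)
        f0 = fit_cox(tab, ["treat"] + covs, start="start", stop="stop",
                     event="event", id_col="id")
        np.testing.assert_allclose(f1.coef, f0.coef, rtol=1e-10)

    def test_randomised_initiation_weighting_changes_little(self):
        """With initiation independent of covariates there is nothing to
        correct: weighted and unweighted estimates agree within 2 SE."""
        from sectrend.config import CovariateSpec, ScenarioConfig
        cfg = ScenarioConfig(
            n_subjects=20_000, baseline_event_hazard=0.04,
            baseline_initiation_hazard=0.10, treatment_log_hr=-0.3,
            covariates=[CovariateSpec("z", "continuous", drift_sd=0.4,
                                      outcome_log_hr=0.3)],
            seed=8)
        cohort = simulate_cohort(cfg)
        base = derive_baseline_cohort(cohort, cfg.window_years,
                                      values=cohort.values)
        init = effective_initiation(cohort, base)
        tab = build_interval_table(base, cohort, dict(cohort.values), init)
        it = build_initiation_table(tab, init)
        den, num = fit_initiation_models(it, ["xk_z", "x0_z"], ["x0_z"])
        ws = compute_stabilised_weights(
            tab, it, interval_probabilities(num, it),
            interval_probabilities(den, it))
        f_w = fit_msm(tab, ["x0_z"], ws)
        f_u = fit_msm(tab, ["x0_z"], None)
        j = f_w.names.index("treat")
        se = max(f_w.se()[j], f_u.se(robust=True)[j])
        assert abs(f_w.coef[j] - f_u.coef[j]) < 2 * se
        # mean stabilised weight ~ 1 (pseudo-population preserved)
        assert 0.95 < ws.diagnostics()["mean"] < 1.05
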