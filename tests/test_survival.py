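"""Unit tests for the weighted counting-process Cox engine and the
nonparametric estimators."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxTimeVaryingFitter

from sectrend import (ConvergenceError, CoxError, breslow_baseline, fit_cox,
                      kaplan_meier, nelson_aalen, predict_risk)
from sectrend.survival import StepFunction

from conftest import grid_search_beta


@pytest.fixture
def four_row():
    # times/events (1,1,x=0) (2,1,x=1) (3,0,x=0) (4,1,x=1)
    return pd.DataFrame({
        "start": [0.0, 0.0, 0.0, 0.0],
        "stop": [1.0, 2.0, 3.0, 4.0],
        "event": [1, 1, 0, 1],
        "x": [0.0, 1.0, 0.0, 1.0],
    })


class TestFitCox:
    def test_matches_grid_search_oracle(self, four_row):
        fit = fit_cox(four_row, ["x"])
        oracle = grid_search_beta(four_row)
        assert abs(fit.coef[0] - oracle) < 1e-3

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_grid_search_with_ties_and_weights(self, ties):
        df = pd.DataFrame({
            "start": [0.0] * 6,
            "stop": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
            "event": [1, 1, 1, 0, 1, 0],
            "x": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
            "w": [1.0, 2.0, 1.0, 0.5, 1.5, 1.0],
        })
        fit = fit_cox(df, ["x"], weight="w", ties=ties)
        oracle = grid_search_beta(df, ties=ties)
        assert abs(fit.coef[0] - oracle) < 1e-3

    def test_unit_weights_match_unweighted(self, simple_surv):
        df = simple_surv.assign(w=1.0)
        f0 = fit_cox(simple_surv, ["x"])
        f1 = fit_cox(df, ["x"], weight="w")
        np.testing.assert_allclose(f0.coef, f1.coef, rtol=1e-12)

    def test_duplicated_half_weight_invariance(self, simple_surv):
        """Splitting every row into two half-weight copies leaves the
        weighted partial likelihood, hence the estimate, unchanged
        (Breslow ties: exact)."""
        dup = pd.concat([simple_surv, simple_surv]).reset_index(drop=True)
        dup["w"] = 0.5
        f0 = fit_cox(simple_surv, ["x"], ties="breslow")
        f1 = fit_cox(dup, ["x"], weight="w", ties="breslow")
        np.testing.assert_allclose(f0.coef, f1.coef, atol=1e-10)

    def test_agrees_with_lifelines_time_varying(self):
        rng = np.random.default_rng(3)
        n = 1500
        x = rng.normal(size=n)
        z = rng.binomial(1, 0.4, n).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x - 0.3 * z)))
        stop = np.minimum(t, 4.0)
        df = pd.DataFrame({"id": np.arange(n), "start": 0.0, "stop": stop,
                           "event": (t <= 4.0).astype(int), "x": x, "z": z})
        fit = fit_cox(df, ["x", "z"], id_col="id")
        ctv = CoxTimeVaryingFitter()
        ctv.fit(df, id_col="id", event_col="event", start_col="start",
                stop_col="stop")
        np.testing.assert_allclose(fit.coef, ctv.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se(robust=False),
                                   ctv.standard_errors_.values, atol=1e-6)

    def test_delayed_entry_risk_sets(self):
        """A late entrant must not appear in earlier risk sets."""
        df = pd.DataFrame({
            "start": [0.0, 0.0, 2.5, 0.0],
            "stop": [4.0, 2.0, 5.0, 5.5],
            "event": [1, 1, 1, 1],
            "x": [1.0, 0.0, 0.0, 1.0],
        })
        fit = fit_cox(df, ["x"], max_iter=200)
        oracle = grid_search_beta(df)
        assert abs(fit.coef[0] - oracle) < 1e-3
        # ignoring the delayed entry must change the risk sets and the fit
        naive = fit_cox(df.assign(start=0.0), ["x"], max_iter=200)
        assert abs(naive.coef[0] - fit.coef[0]) > 1e-3

    def test_nested_likelihood_ratio_nonnegative(self, simple_surv):
        rng = np.random.default_rng(1)
        df = simple_surv.assign(z=rng.normal(size=len(simple_surv)))
        small = fit_cox(df, ["x"], compute_baseline=False)
        big = fit_cox(df, ["x", "z"], compute_baseline=False)
        assert 2 * (big.loglik - small.loglik) >= -1e-9

    def test_error_conditions(self, simple_surv):
        with pytest.raises(CoxError, match="no events"):
            fit_cox(simple_surv.assign(event=0), ["x"])
        with pytest.raises(CoxError, match="constant"):
            fit_cox(simple_surv.assign(c=1.0), ["c"])
        bad = simple_surv.copy()
        bad.loc[0, "stop"] = bad.loc[0, "start"]
        with pytest.raises(CoxError, match="start"):
            fit_cox(bad, ["x"])
        with pytest.raises(CoxError, match="weights"):
            fit_cox(simple_surv.assign(w=0.0), ["x"], weight="w")

    def test_json_round_trip(self, simple_surv):
        from sectrend.survival import CoxFit
        fit = fit_cox(simple_surv, ["x"])
        clone = CoxFit.from_dict(fit.to_dict())
        np.testing.assert_allclose(clone.coef, fit.coef)
        X = simple_surv[["x"]]
        np.testing.assert_allclose(predict_risk(clone, X, 4.0),
                                   predict_risk(fit, X, 4.0))


class TestBreslowBaseline:
    def test_reduces_to_nelson_aalen_at_null(self):
        """With a single near-null covariate, no ties and unit weights, the
        Breslow baseline equals the Nelson-Aalen estimator."""
        rng = np.random.default_rng(5)
        n = 300
        t = rng.exponential(4.0, n)
        stop = np.minimum(t, 5.0)
        ev = t <= 5.0
        # independent covariate with a forced zero coefficient: fit on a
        # permuted copy so beta ~ 0, then override to exactly 0
        df = pd.DataFrame({"start": 0.0, "stop": stop, "event": ev.astype(int),
                           "x": rng.normal(size=n)})
        fit = fit_cox(df, ["x"])
        fit.coef = np.zeros(1)
        H = breslow_baseline(fit, df)
        _, na = nelson_aalen(stop, ev)
        grid = np.linspace(0.1, 5.0, 40)
        np.testing.assert_allclose(H(grid), na(grid), atol=1e-10)

    def test_single_event_increment(self):
        df = pd.DataFrame({"start": [0.0] * 5, "stop": [1, 2, 3, 4, 5.0],
                           "event": [1, 0, 0, 0, 0], "x": [0, 1, 0, 1, 0.0]})
        fit = fit_cox(df, ["x"])
        fit.coef = np.zeros(1)
        H = breslow_baseline(fit, df)
        assert H(1.0) == pytest.approx(1 / 5)

    def test_nondecreasing(self, simple_surv):
        fit = fit_cox(simple_surv, ["x"])
        assert np.all(np.diff(fit.baseline.values) >= -1e-15)
        assert fit.baseline(0.0) == 0.0


class TestPredictRisk:
    def test_formula(self):
        fit_like = fit_cox(pd.DataFrame({
            "start": [0.0] * 4, "stop": [1.0, 2, 3, 4],
            "event": [1, 1, 0, 1], "x": [0.0, 1, 0, 1]}), ["x"])
        fit_like.baseline = StepFunction(np.array([1.0]), np.array([0.02]))
        fit_like.t_max = 6.0
        fit_like.coef = np.array([np.log(2.0)])
        fit_like.means = np.array([0.0])
        risk = predict_risk(fit_like, pd.DataFrame({"x": [1.0]}), horizon=5)
        assert risk[0] == pytest.approx(1 - np.exp(-0.04), abs=1e-12)
        # zero linear predictor
        risk0 = predict_risk(fit_like, pd.DataFrame({"x": [0.0]}), horizon=5)
        assert risk0[0] == pytest.approx(1 - np.exp(-0.02), abs=1e-12)

    def test_monotone_in_linear_predictor(self, simple_surv):
        fit = fit_cox(simple_surv, ["x"])
        xs = pd.DataFrame({"x": np.linspace(-2, 2, 9)})
        r = predict_risk(fit, xs, horizon=4.0)
        sign = np.sign(fit.coef[0])
        assert np.all(np.diff(r) * sign > 0)

    def test_horizon_beyond_data_errors(self, simple_surv):
        fit = fit_cox(simple_surv, ["x"])
        with pytest.raises(CoxError, match="horizon"):
            predict_risk(fit, simple_surv[["x"]], horizon=50.0)


class TestNonparametric:
    def test_km_hand_example(self):
        # events at t=2 (3 at risk) and t=5 (1 at risk), censor at 3
        km = kaplan_meier([2.0, 3.0, 5.0], [1, 0, 1])
        assert km.survival_at(2.0) == pytest.approx(2 / 3)
        assert km.survival_at(5.0) == pytest.approx(0.0)

    def test_km_no_events(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at(3.0) == pytest.approx(1.0)

    def test_km_all_events_is_empirical(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        km = kaplan_meier(times, np.ones(4))
        for t in times:
            assert km.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_nelson_aalen_hand_examples(self):
        per, sf = nelson_aalen([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        # H(1) = 1/4, H(3) = 1/4 + 1/2
        assert sf(1.0) == pytest.approx(0.25)
        assert sf(3.0) == pytest.approx(0.75)
        np.testing.assert_allclose(per, [0.25, 0.25, 0.75, 0.75])
        per1, _ = nelson_aalen([2.0], [1])
        assert per1[0] == pytest.approx(1.0)
        per0, sf0 = nelson_aalen([1.0, 2.0], [0, 0])
        assert sf0(5.0) == 0.0
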