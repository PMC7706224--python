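"""Core survival estimators.

The centrepiece is a weighted Cox partial-likelihood fitter for
counting-process (start, stop] data — the estimator every analysis in this
package runs through: the baseline risk models, the calendar-time trend
model, the treatment-initiation models behind the IPT weights, and the
weighted marginal structural fits.  It supports case weights, delayed
entry, Efron or Breslow tie handling, a weighted Breslow baseline
cumulative hazard, and a cluster-robust (sandwich) covariance for weighted
fits.

Kaplan–Meier and Nelson–Aalen estimation are delegated to lifelines;
the Nelson–Aalen estimator is also returned per subject at their own exit
time because the imputation model uses it as an auxiliary variable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter, NelsonAalenFitter


class CoxError(ValueError):
    pass


class ConvergenceError(CoxError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass
class StepFunction:
    """Right-continuous non-decreasing step function with value 0 before the
    first jump (a cumulative hazard)."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.maximum(idx, 0)], 0.0)
        return float(out) if t.ndim == 0 else out


@dataclass
class CoxFit:
    """A fitted (possibly weighted) counting-process Cox model."""

    names: list
    coef: np.ndarray
    var_model: np.ndarray
    means: np.ndarray               # centring constants (weighted covariate means)
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    converged: bool
    n_iter: int
    var_robust: np.ndarray | None = None
    baseline: StepFunction | None = None
    t_max: float = np.nan
    weighted: bool = False

    def se(self, robust: bool | None = None) -> np.ndarray:
        use_robust = self.weighted if robust is None else robust
        v = self.var_robust if (use_robust and self.var_robust is not None) \
            else self.var_model
        return np.sqrt(np.diag(v))

    def linear_predictor(self, X) -> np.ndarray:
        X = _design_from(X, self.names)
        return (X - self.means) @ self.coef

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef,
            "se(model)": np.sqrt(np.diag(self.var_model)),
            "se(robust)": (np.sqrt(np.diag(self.var_robust))
                           if self.var_robust is not None else np.nan),
            "hr": np.exp(self.coef),
        }, index=self.names)

    # -- JSON round trip (fitted-model files) ---------------------------
    def to_dict(self) -> dict:
        d = {
            "names": list(self.names),
            "coef": self.coef.tolist(),
            "var_model": self.var_model.tolist(),
            "var_robust": None if self.var_robust is None else self.var_robust.tolist(),
            "means": self.means.tolist(),
            "loglik": self.loglik, "loglik_null": self.loglik_null,
            "n": self.n, "n_events": self.n_events, "ties": self.ties,
            "converged": self.converged, "n_iter": self.n_iter,
            "t_max": self.t_max, "weighted": self.weighted,
            "baseline": None if self.baseline is None else
                [self.baseline.times.tolist(), self.baseline.values.tolist()],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CoxFit":
        base = d.pop("baseline", None)
        fit = cls(names=d["names"], coef=np.asarray(d["coef"]),
                  var_model=np.asarray(d["var_model"]),
                  means=np.asarray(d["means"]), loglik=d["loglik"],
                  loglik_null=d["loglik_null"], n=d["n"],
                  n_events=d["n_events"], ties=d["ties"],
                  converged=d["converged"], n_iter=d["n_iter"],
                  var_robust=None if d.get("var_robust") is None
                  else np.asarray(d["var_robust"]),
                  t_max=d.get("t_max", np.nan),
                  weighted=d.get("weighted", False))
        if base is not None:
            fit.baseline = StepFunction(np.asarray(base[0]), np.asarray(base[1]))
        return fit


def _design_from(X, names):
    if isinstance(X, pd.DataFrame):
        return X[list(names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return X.reshape(-1, len(names)) if X.ndim == 1 and len(names) == 1 else X


# ---------------------------------------------------------------------------
# internal machinery shared by loglik / score / information / baseline

class _CoxData:
    """Static sorting/grouping structures; independent of beta."""

    def __init__(self, start, stop, event, X, w, ties):
        self.start, self.stop, self.event = start, stop, event
        self.X, self.w, self.ties = X, w, ties
        self.n, self.p = X.shape

        self.et = np.unique(stop[event])            # ordered unique event times
        self.m = len(self.et)
        self.ord_stop = np.argsort(stop, kind="stable")
        self.ord_start = np.argsort(start, kind="stable")
        sorted_stop = stop[self.ord_stop]
        sorted_start = start[self.ord_start]
        # rows in the risk set at t: start < t <= stop
        self.i_stop = np.searchsorted(sorted_stop, self.et, side="left")
        self.i_start = np.searchsorted(sorted_start, self.et, side="left")

        # death rows grouped by event time
        didx = np.flatnonzero(event)
        self.dsort = didx[np.argsort(stop[didx], kind="stable")]
        dstop = stop[self.dsort]
        self.bnd = np.searchsorted(dstop, self.et, side="left")
        self.d = np.diff(np.append(self.bnd, len(self.dsort)))  # ties per time

        # Efron expansion over (event time, l) pairs
        self.idx_t = np.repeat(np.arange(self.m), self.d)
        self.frac = np.concatenate([np.arange(dk) / dk for dk in self.d]) \
            if self.m else np.empty(0)
        self.Wd = np.add.reduceat(w[self.dsort], self.bnd) if self.m else np.empty(0)
        self.wbar = (self.Wd / self.d)[self.idx_t]

    def suffix(self, v):
        """For each event time t: sum of v over rows with start < t <= stop."""
        a = np.concatenate([np.cumsum(v[self.ord_stop][::-1])[::-1], [0.0]])
        b = np.concatenate([np.cumsum(v[self.ord_start][::-1])[::-1], [0.0]])
        return a[self.i_stop] - b[self.i_start]

    def group_d(self, v):
        """Sum of v over tied death rows, per event time."""
        return np.add.reduceat(v[self.dsort], self.bnd)

    def quantities(self, beta, need_info=True):
        """Weighted partial log-likelihood, score and information at beta."""
        X, w = self.X, self.w
        eta = X @ beta if self.p else np.zeros(self.n)
        r = w * np.exp(eta)
        p, m = self.p, self.m

        S0 = self.suffix(r)
        S1 = np.empty((m, p))
        for j in range(p):
            S1[:, j] = self.suffix(r * X[:, j])

        Sd0 = self.group_d(r)
        Sd1 = np.empty((m, p))
        for j in range(p):
            Sd1[:, j] = self.group_d(r * X[:, j])

        if self.ties == "efron":
            it, frac, wbar = self.idx_t, self.frac, self.wbar
            Z0 = S0[it] - frac * Sd0[it]
            Z1 = S1[it] - frac[:, None] * Sd1[it]
        else:  # breslow: one term per time, weight Wd
            it = np.arange(m)
            frac = np.zeros(m)
            wbar = self.Wd
            Z0, Z1 = S0, S1

        if np.any(Z0 <= 0):
            return -np.inf, None, None
        ll = float(np.sum(w[self.dsort] * eta[self.dsort]) - np.sum(wbar * np.log(Z0)))
        if not need_info:
            return ll, None, None

        sum_wx = np.array([np.sum(w[self.dsort] * X[self.dsort, j])
                           for j in range(p)])
        ratio = Z1 / Z0[:, None]
        U = sum_wx - (wbar[:, None] * ratio).sum(axis=0)

        info = np.zeros((p, p))
        for a in range(p):
            Sa = self.suffix(r * X[:, a] * X[:, a])
            Sda = self.group_d(r * X[:, a] * X[:, a])
            Z2 = (Sa[it] - frac * Sda[it]) if self.ties == "efron" else Sa
            info[a, a] = np.sum(wbar * (Z2 / Z0 - ratio[:, a] ** 2))
            for b in range(a + 1, p):
                Sab = self.suffix(r * X[:, a] * X[:, b])
                Sdab = self.group_d(r * X[:, a] * X[:, b])
                Z2 = (Sab[it] - frac * Sdab[it]) if self.ties == "efron" else Sab
                val = np.sum(wbar * (Z2 / Z0 - ratio[:, a] * ratio[:, b]))
                info[a, b] = info[b, a] = val
        return ll, U, info

    def baseline_increments(self, beta):
        """Weighted Breslow (Efron-corrected) baseline hazard increments."""
        eta = self.X @ beta if self.p else np.zeros(self.n)
        r = self.w * np.exp(eta)
        S0 = self.suffix(r)
        Sd0 = self.group_d(r)
        if self.ties == "efron":
            Z0 = S0[self.idx_t] - self.frac * Sd0[self.idx_t]
            per_pair = self.wbar / Z0
            dH = np.zeros(self.m)
            np.add.at(dH, self.idx_t, per_pair)
        else:
            dH = self.Wd / S0
        return dH

    def schoenfeld_style_residuals(self, beta):
        """Per-row score residuals (Breslow-form approximation; used only
        for the sandwich covariance)."""
        eta = self.X @ beta if self.p else np.zeros(self.n)
        r = self.w * np.exp(eta)
        S0 = self.suffix(r)
        S1 = np.column_stack([self.suffix(r * self.X[:, j]) for j in range(self.p)]) \
            if self.p else np.empty((self.m, 0))
        xbar = S1 / S0[:, None]
        dH = self.Wd / S0
        G0 = np.concatenate([[0.0], np.cumsum(dH)])
        G1 = np.vstack([np.zeros(self.p), np.cumsum(xbar * dH[:, None], axis=0)])
        hi = np.searchsorted(self.et, self.stop, side="right")
        lo = np.searchsorted(self.et, self.start, side="right")
        a = G0[hi] - G0[lo]
        b = G1[hi] - G1[lo]
        # event-time covariate mean for each death row
        pos = np.searchsorted(self.et, self.stop)
        dev = np.zeros((self.n, self.p))
        drows = self.dsort
        dev[drows] = self.X[drows] - xbar[pos[drows]]
        resid = (self.w[:, None] * self.event[:, None] * dev
                 - r[:, None] * (self.X * a[:, None] - b))
        return resid


def _extract(df, covariates, start, stop, event, weight, id_col):
    s = df[start].to_numpy(dtype=float)
    t = df[stop].to_numpy(dtype=float)
    e = df[event].to_numpy(dtype=bool)
    X = df[list(covariates)].to_numpy(dtype=float) if covariates \
        else np.empty((len(df), 0))
    w = (df[weight].to_numpy(dtype=float) if weight is not None
         else np.ones(len(df)))
    ids = df[id_col].to_numpy() if id_col is not None else np.arange(len(df))
    return s, t, e, X, w, ids


def fit_cox(df: pd.DataFrame, covariates, start="start", stop="stop",
            event="event", weight=None, id_col=None, ties="efron",
            max_iter=100, tol_score=1e-9, tol_ll=1e-10, robust=None,
            compute_baseline=True) -> CoxFit:
    """Fit a weighted Cox model to counting-process rows by Newton–Raphson.

    Maximises the weighted partial likelihood (Efron ties by default) with
    step-halving; converges when ``max|score| < tol_score`` or the relative
    log-likelihood change drops below ``tol_ll``.  A cluster-robust sandwich
    covariance (clustered on ``id_col`` when given, else on rows) is
    computed whenever any weight differs from 1, or on request.

    Raises
    ------
    CoxError
        for no events, invalid intervals/weights, or a constant column.
    ConvergenceError
        if Newton–Raphson fails within ``max_iter`` (carries the
        log-likelihood trace).
    """
    covariates = list(covariates)
    s, t, e, X, w, ids = _extract(df, covariates, start, stop, event,
                                  weight, id_col)
    if np.any(~np.isfinite(X)):
        bad = [covariates[j] for j in range(X.shape[1])
               if np.any(~np.isfinite(X[:, j]))]
        raise CoxError(f"non-finite values in covariates {bad}")
    if np.any(t <= s):
        raise CoxError("stop must be strictly greater than start for every row")
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise CoxError("weights must be strictly positive and finite")
    if e.sum() < 1:
        raise CoxError("no events in the data")
    if ties not in ("efron", "breslow"):
        raise CoxError(f"unknown ties method {ties!r}")

    wsum = w.sum()
    means = (w @ X) / wsum if X.size else np.zeros(X.shape[1])
    Xc = X - means
    for j, name in enumerate(covariates):
        if Xc.size and float(w @ (Xc[:, j] ** 2)) / wsum < 1e-12:
            raise CoxError(f"constant covariate column: {name!r}")

    data = _CoxData(s, t, e, Xc, w, ties)
    p = Xc.shape[1]
    beta = np.zeros(p)
    ll, U, info = data.quantities(beta)
    ll_null = ll
    trace = [ll]
    n_iter = 0
    converged = p == 0
    for n_iter in range(1, max_iter + 1):
        if p == 0:
            break
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {n_iter}",
                trace) from exc
        new_ll = -np.inf
        for _ in range(25):
            cand = beta + step
            new_ll, newU, newI = data.quantities(cand)
            if np.isfinite(new_ll) and new_ll >= ll - 1e-12:
                break
            step = step / 2.0
        if not np.isfinite(new_ll):
            raise ConvergenceError("step-halving failed to find an uphill step",
                                   trace)
        beta, rel = cand, abs(new_ll - ll) / (abs(ll) + 1e-10)
        ll, U, info = new_ll, newU, newI
        trace.append(ll)
        if np.max(np.abs(U)) < tol_score or rel < tol_ll:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations", trace)

    var_model = np.linalg.inv(info) if p else np.zeros((0, 0))
    weighted = bool(np.any(w != 1.0))
    fit = CoxFit(names=covariates, coef=beta, var_model=var_model, means=means,
                 loglik=ll, loglik_null=ll_null, n=len(df),
                 n_events=int(e.sum()), ties=ties, converged=converged,
                 n_iter=n_iter, t_max=float(t.max()), weighted=weighted)

    if (robust is None and weighted) or robust:
        resid = data.schoenfeld_style_residuals(beta)
        codes, _ = pd.factorize(ids)
        Ug = np.zeros((codes.max() + 1, p))
        np.add.at(Ug, codes, resid)
        meat = Ug.T @ Ug
        fit.var_robust = var_model @ meat @ var_model if p else np.zeros((0, 0))

    if compute_baseline:
        dH = data.baseline_increments(beta)
        fit.baseline = StepFunction(data.et.copy(), np.cumsum(dH))
    return fit


def breslow_baseline(fit: CoxFit, df: pd.DataFrame, start="start", stop="stop",
                     event="event", weight=None) -> StepFunction:
    """Weighted Breslow baseline cumulative hazard of ``fit`` on its rows.

    ``dH0(t) = (weighted events at t) / (risk-set weighted sum of exp(lp))``
    with the Efron correction when the fit used Efron ties.  The rows must
    be those the model was fitted to.
    """
    s, t, e, X, w, _ = _extract(df, fit.names, start, stop, event, weight, None)
    if len(df) != fit.n or int(e.sum()) != fit.n_events:
        raise CoxError("rows do not match the fitted model (n or event count)")
    data = _CoxData(s, t, e, X - fit.means, w, fit.ties)
    dH = data.baseline_increments(fit.coef)
    sf = StepFunction(data.et.copy(), np.cumsum(dH))
    fit.baseline = sf
    fit.t_max = float(t.max())
    return sf


def predict_risk(fit: CoxFit, X, horizon: float = 5.0) -> np.ndarray:
    """Absolute event risk by ``horizon``: 1 - exp(-H0(horizon) e^lp).

    ``X`` supplies the covariate columns named in the fit (a DataFrame or
    array in fit order); the linear predictor is centred exactly as at fit
    time, so predictions are reproducible from the serialised model.
    """
    if fit.baseline is None:
        raise CoxError("fit has no baseline hazard; run breslow_baseline first")
    if not np.isfinite(fit.t_max) or horizon > fit.t_max + 1e-12:
        raise CoxError(
            f"horizon {horizon} lies beyond the last observed time {fit.t_max}")
    lp = fit.linear_predictor(X)
    H = fit.baseline(horizon)
    return 1.0 - np.exp(-H * np.exp(lp))


# ---------------------------------------------------------------------------
# nonparametric estimators (lifelines-backed)

@dataclass
class KMEstimate:
    """Kaplan–Meier product-limit estimate with Greenwood-based 95% CIs."""

    kmf: KaplanMeierFitter = field(repr=False)

    def survival_at(self, t) -> np.ndarray:
        return np.asarray(self.kmf.predict(t), dtype=float)

    def risk_at(self, t) -> np.ndarray:
        return 1.0 - self.survival_at(t)

    def risk_ci_at(self, t) -> tuple:
        ci = self.kmf.confidence_interval_survival_function_
        lo_s = np.interp(t, ci.index.values, ci.iloc[:, 0].values)
        hi_s = np.interp(t, ci.index.values, ci.iloc[:, 1].values)
        # survival CI flips under the risk = 1 - S transform
        return 1.0 - hi_s, 1.0 - lo_s


def kaplan_meier(times, events, alpha=0.05) -> KMEstimate:
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    return KMEstimate(kmf)


def nelson_aalen(times, events) -> tuple:
    """Nelson–Aalen cumulative hazard ``H(t) = sum d_j / n_j``.

    Returns ``(per_subject, step_function)`` where ``per_subject[i]`` is H
    evaluated at subject i's own exit time — the auxiliary variable the
    stochastic imputation model includes.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
    naf.fit(times, events)
    ch = naf.cumulative_hazard_
    sf = StepFunction(ch.index.to_numpy(dtype=float),
                      ch.iloc[:, 0].to_numpy(dtype=float))
    return sf(times), sf
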