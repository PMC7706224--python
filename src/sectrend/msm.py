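"""Marginal structural Cox model machinery.

Treatment initiation during follow-up ("drop-in") that depends on evolving
covariates confounds any naive adjustment.  The remedy implemented here:
fit time-to-initiation Cox models on the untreated person-time — a
*denominator* model using time-varying and baseline covariates, and a
*numerator* model using baseline covariates only (plus calendar time when
the outcome model includes it) — convert each to per-interval conditional
initiation probabilities, and form stabilised inverse-probability-of-
treatment weights

    sw_iK = prod_{k<=K} (p*_k)^{A_k} (1-p*_k)^{1-A_k}
          / prod_{k<=K} (p_k)^{A_k}  (1-p_k)^{1-A_k}

Treatment is absorbing, so every factor after the initiation interval is 1
and the weight is constant from then on.  The weighted counting-process
Cox fit of the outcome on baseline covariates and current treatment status
then estimates the causal (log) hazard ratio of initiation, and its
Breslow baseline yields counterfactual never-treated risks
E[Y(Abar = 0) | X0].

The Cox-to-probability transform — the per-interval conditional initiation
probability p = 1 - exp(-dH0(k) e^lp), with dH0(k) the Breslow baseline
increment over interval k — is this package's documented choice of
discretisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import INTERVAL_YEARS
from .survival import CoxError, CoxFit, fit_cox, predict_risk


class PositivityError(ValueError):
    pass


@dataclass
class WeightSet:
    """Per subject-interval stabilised weights, aligned to an interval table."""

    table_index: np.ndarray         # row index of the interval table
    sw: np.ndarray                  # stabilised weight per row
    p_num: np.ndarray               # numerator probability (NaN on treated rows)
    p_den: np.ndarray
    factor: np.ndarray              # this interval's contribution (1 on treated rows)
    truncation: tuple | None = None
    bounds: tuple | None = None
    n_truncated: int = 0

    def diagnostics(self) -> dict:
        return {
            "mean": float(np.mean(self.sw)),
            "sd": float(np.std(self.sw)),
            "min": float(np.min(self.sw)),
            "max": float(np.max(self.sw)),
            "n": int(len(self.sw)),
            "n_truncated": int(self.n_truncated),
            "truncation": self.truncation,
            "bounds": self.bounds,
        }


def build_initiation_table(intervals: pd.DataFrame,
                           init_times: pd.Series) -> pd.DataFrame:
    """Time-to-initiation rows: untreated person-time only.

    Rows of the interval table with ``treat == 0``, stopped at the
    initiation time when it falls inside the interval, with ``init_event``
    flagging that initiation.
    """
    out = intervals[intervals["treat"] == 0].copy()
    init = init_times.reindex(out["id"]).to_numpy(dtype=float)
    start = out["start"].to_numpy()
    stop = out["stop"].to_numpy()
    with np.errstate(invalid="ignore"):
        inside = ~np.isnan(init) & (init > start) & (init <= stop)
    out["init_event"] = inside.astype(int)
    out["init_stop"] = np.where(inside, init, stop)
    return out


def fit_initiation_models(init_table: pd.DataFrame, denom_covariates,
                          numer_covariates, ties="efron") -> tuple[CoxFit, CoxFit]:
    """Denominator and numerator treatment models (interval Cox fits).

    The denominator conditions on time-varying plus baseline covariates;
    the numerator on baseline covariates only (a subset, by construction).
    Raises on zero initiations; warns when a coefficient exceeds 10 in
    absolute value (a separation signal).
    """
    if init_table["init_event"].sum() == 0:
        raise CoxError("no treatment initiations: cannot fit weight models")
    missing = set(numer_covariates) - set(denom_covariates)
    if missing:
        raise ValueError(
            f"numerator covariates must be a subset of denominator ones; "
            f"extra: {sorted(missing)}")

    def _fit(covs):
        # drop exactly duplicated columns (e.g. x0_ == xk_ for static covariates)
        kept, seen = [], []
        for c in covs:
            col = init_table[c].to_numpy()
            if any(np.array_equal(col, s) for s in seen):
                continue
            kept.append(c)
            seen.append(col)
        fit = fit_cox(init_table, kept, start="start", stop="init_stop",
                      event="init_event", id_col="id", ties=ties)
        for name, b in zip(fit.names, fit.coef):
            if abs(b) > 10:
                warnings.warn(f"possible separation in weight model: "
                              f"|coef({name})| = {abs(b):.1f} > 10",
                              RuntimeWarning)
        return fit

    return _fit(list(denom_covariates)), _fit(list(numer_covariates))


def interval_probabilities(fit: CoxFit, rows: pd.DataFrame) -> np.ndarray:
    """Conditional probability of initiating within each row's interval.

    ``p = 1 - exp(-dH0(k) * exp(lp))`` with ``dH0(k)`` the fitted model's
    baseline cumulative-hazard increment across interval k.
    """
    if fit.baseline is None:
        raise CoxError("initiation model has no baseline hazard")
    k = rows["k"].to_numpy()
    dH = fit.baseline((k + 1) * INTERVAL_YEARS) - fit.baseline(k * INTERVAL_YEARS)
    if np.any(dH < -1e-12):
        raise AssertionError("negative baseline-hazard increment")
    lp = fit.linear_predictor(rows)
    return 1.0 - np.exp(-np.maximum(dH, 0.0) * np.exp(lp))


def compute_stabilised_weights(intervals: pd.DataFrame,
                               init_table: pd.DataFrame,
                               p_num: np.ndarray, p_den: np.ndarray,
                               truncation: tuple | None = None) -> WeightSet:
    """Stabilised IPT weight for every row of the interval table.

    The transition observed during initiation-risk interval k determines
    the treatment status A_{k+1} at the next interval start, and
    contributes the factor ``p*/p`` (initiation) or ``(1-p*)/(1-p)``
    (still untreated).  The weight carried by an outcome row is the
    cumulative product of the factors for the statuses *up to its start*
    — the transition unfolding within the row's own interval (which may
    be cut short by the event) is not part of its weight.  Treatment is
    absorbing, so the weight is constant from the first treated row
    onward.  Optional symmetric percentile ``truncation`` (e.g. (1, 99))
    is applied last.
    """
    if np.any(p_den >= 1.0):
        raise PositivityError("denominator probability of 1: positivity violated")
    if np.any(p_num >= 1.0):
        raise PositivityError("numerator probability of 1")

    a = init_table["init_event"].to_numpy(dtype=bool)
    factor = np.where(a, p_num / p_den, (1.0 - p_num) / (1.0 - p_den))

    # per-row factor on the full table (treated rows contribute 1), then an
    # exclusive cumulative product within subject
    fac = pd.Series(1.0, index=intervals.index, dtype=float)
    fac.loc[init_table.index] = factor
    logf = np.log(fac.to_numpy())
    ids = intervals["id"].to_numpy()
    cum = np.cumsum(logf)
    first = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
    offset = np.repeat(np.r_[0.0, cum[first[1:] - 1]],
                       np.diff(np.r_[first, len(ids)]))
    inclusive = cum - offset
    exclusive = inclusive - logf
    sw = np.exp(exclusive)

    pn = pd.Series(np.nan, index=intervals.index, dtype=float)
    pn.loc[init_table.index] = p_num
    pd_ = pd.Series(np.nan, index=intervals.index, dtype=float)
    pd_.loc[init_table.index] = p_den

    ws = WeightSet(table_index=intervals.index.to_numpy(), sw=sw,
                   p_num=pn.to_numpy(), p_den=pd_.to_numpy(),
                   factor=fac.to_numpy(), truncation=truncation)
    if truncation is not None:
        lo, hi = np.percentile(sw, truncation)
        ws.n_truncated = int(np.sum((sw < lo) | (sw > hi)))
        ws.sw = np.clip(sw, lo, hi)
        ws.bounds = (float(lo), float(hi))
    return ws


def fit_msm(intervals: pd.DataFrame, covariates, weights: WeightSet | None = None,
            treat_col: str = "treat", ties: str = "efron") -> CoxFit:
    """Weighted (or, with ``weights=None``, the unweighted comparator)
    counting-process Cox fit of the outcome on treatment status and the
    given baseline-covariate design columns, with cluster-robust SEs."""
    work = intervals.copy()
    covs = [treat_col] + list(covariates)
    if weights is not None:
        work["_sw"] = weights.sw
    return fit_cox(work, covs, start="start", stop="stop", event="event",
                   weight="_sw" if weights is not None else None,
                   id_col="id", ties=ties, robust=True)


def counterfactual_risk(msm_fit: CoxFit, X0: pd.DataFrame,
                        horizon: float = 5.0, treat_col: str = "treat") -> np.ndarray:
    """Never-treated risk E[Y(Abar=0) | X0]: predict with A fixed at 0."""
    X = X0.copy()
    X[treat_col] = 0.0
    return predict_risk(msm_fit, X, horizon=horizon)
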