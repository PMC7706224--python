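"""Three-stage missing-data cascade.

1.  Last observation carried forward (LOCF) within each subject's
    half-year covariate path;
2.  next observation carried backwards (NOCB) for what remains;
3.  a single *stochastic* chained-equations imputation at baseline for
    variables missing at every time point, whose draws are then copied to
    all later time points.

The chained-equations step imputes each incomplete variable from all other
covariates plus two auxiliaries — the Nelson–Aalen cumulative hazard at
the subject's exit and the event indicator — using Bayesian linear-model
draws for continuous variables and logistic draws for binary ones (a draw
from the posterior predictive, never a conditional mean).  One completed
dataset is produced; observed values are never altered at any stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit


class ImputationError(ValueError):
    pass


def locf_then_nocb(values: dict, mask: dict) -> tuple[dict, dict]:
    """Forward-fill then backward-fill each subject's path per variable.

    ``values``/``mask`` map variable name -> (n, K) arrays.  Returns
    ``(filled, residual)`` where ``residual`` marks entries still missing
    (variables absent at all K time points for a subject — these fall
    through to the stochastic baseline imputation).  Observed entries are
    returned unchanged.
    """
    filled, residual = {}, {}
    for name, vals in values.items():
        v = vals.astype(float).copy()
        v[mask[name]] = np.nan
        f = pd.DataFrame(v).ffill(axis=1).bfill(axis=1).to_numpy()
        filled[name] = f
        residual[name] = np.isnan(f)
    return filled, residual


def _bayes_linear_draw(Xo, yo, Xm, rng):
    """Posterior-predictive draw from a normal linear model (noninformative
    prior): sigma^2 from scaled inverse chi-square, beta from its normal
    conditional, plus residual noise."""
    n, p = Xo.shape
    beta_hat, _, rank, _ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    df = max(n - rank, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(df, random_state=rng)
    XtX = Xo.T @ Xo + 1e-8 * np.eye(p)
    cov = sigma2 * np.linalg.inv(XtX)
    L = np.linalg.cholesky((cov + cov.T) / 2)
    beta = beta_hat + L @ rng.standard_normal(p)
    return Xm @ beta + rng.normal(0.0, np.sqrt(sigma2), size=len(Xm))


def _logistic_draw(Xo, yo, Xm, rng):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(yo, Xo, family=sm.families.Binomial()).fit(maxiter=50)
        beta = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        L = np.linalg.cholesky((cov + cov.T) / 2 + 1e-10 * np.eye(len(beta)))
        beta = beta + L @ rng.standard_normal(len(beta))
        p = expit(Xm @ beta)
    except Exception:  # separation / singular fit: fall back to marginal rate
        warnings.warn("logistic imputation model failed; drawing from the "
                      "marginal rate", RuntimeWarning)
        p = np.full(len(Xm), float(np.mean(yo)))
    return (rng.random(len(Xm)) < p).astype(float)


def stochastic_baseline_imputation(baseline: pd.DataFrame, kinds: dict,
                                   aux_cols=("na_hazard", "event"),
                                   seed: int = 0, n_cycles: int = 10,
                                   prefix: str = "x0_") -> pd.DataFrame:
    """One stochastic chained-equations imputation of baseline covariates.

    ``kinds`` maps variable name -> "continuous" | "binary" | "categorical".
    Each incomplete variable is modelled on every other covariate plus the
    auxiliary columns; variables are visited in ascending missingness
    order for ``n_cycles`` cycles.  Categorical residual missingness is
    filled by draws from the observed marginal distribution.

    Raises :class:`ImputationError` when a variable is 100% missing (no
    donor information exists).
    """
    rng = np.random.default_rng(seed)
    df = baseline.copy()
    cols = {name: prefix + name for name in kinds}
    miss = {n: df[c].isna().to_numpy() for n, c in cols.items()}
    incomplete = [n for n in kinds if miss[n].any()]
    for n in incomplete:
        if miss[n].all():
            raise ImputationError(
                f"variable {n!r} is missing for every subject; nothing to fit on")
    if not incomplete:
        return df

    # initial fill: random draws from each variable's observed values
    for n in incomplete:
        obs = df.loc[~miss[n], cols[n]].to_numpy()
        df.loc[miss[n], cols[n]] = rng.choice(obs, size=int(miss[n].sum()))

    order = sorted(incomplete, key=lambda n: miss[n].sum())
    aux = df[list(aux_cols)].to_numpy(dtype=float)
    for _ in range(n_cycles):
        for n in order:
            if kinds[n] == "categorical":
                continue  # keep the marginal draws from the initial fill
            others = [cols[o] for o in kinds if o != n]
            X = np.column_stack([np.ones(len(df)),
                                 df[others].to_numpy(dtype=float), aux])
            y = df[cols[n]].to_numpy(dtype=float)
            m = miss[n]
            if kinds[n] == "binary":
                df.loc[m, cols[n]] = _logistic_draw(X[~m], y[~m], X[m], rng)
            else:
                df.loc[m, cols[n]] = _bayes_linear_draw(X[~m], y[~m], X[m], rng)
    return df


def carry_baseline_forward(filled: dict, residual: dict,
                           baseline: pd.DataFrame, cohort_ids,
                           prefix: str = "x0_") -> dict:
    """Copy imputed baseline values into every still-missing time point.

    ``baseline`` is the completed baseline table (stage 3 output); entries
    of ``filled`` flagged in ``residual`` receive that subject's baseline
    value at all K time points.
    """
    pos = pd.Series(np.arange(len(cohort_ids)), index=cohort_ids)
    rows = pos[baseline["id"].to_numpy()].to_numpy()
    out = {}
    for name, path in filled.items():
        p = path.copy()
        col = prefix + name
        if col in baseline.columns:
            base = np.full(len(cohort_ids), np.nan)
            base[rows] = baseline[col].to_numpy(dtype=float)
            r = residual[name]
            p[r] = np.broadcast_to(base[:, None], p.shape)[r]
        out[name] = p
    return out
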