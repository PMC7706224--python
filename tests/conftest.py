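import numpy as np
import pandas as pd
import pytest

from sectrend import builtin_scenario, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized default-scenario cohort shared across tests (read-only)."""
    scenario, study = builtin_scenario("default", n_subjects=20_000)
    cohort = simulate_cohort(scenario, seed=123)
    return cohort, scenario, study


@pytest.fixture
def simple_surv():
    """A small single-covariate survival frame with a known generating model."""
    rng = np.random.default_rng(7)
    n = 800
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1.0 / (0.15 * np.exp(0.5 * x)))
    stop = np.minimum(t, 5.0)
    return pd.DataFrame({
        "id": np.arange(n),
        "start": 0.0,
        "stop": stop,
        "event": (t <= 5.0).astype(int),
        "x": x,
    })


def brute_force_cox_loglik(df, beta, ties="efron"):
    """Independent O(n^2) partial log-likelihood for one covariate.

    Counting-process risk sets (start < t <= stop), Efron or Breslow ties,
    optional case weights.  ``beta`` may be a scalar or a grid (vectorised
    over the last axis).  Used as the grid-search oracle for fit_cox.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    x = df["x"].to_numpy(dtype=float)
    start = df["start"].to_numpy(dtype=float)
    stop = df["stop"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=bool)
    w = df["w"].to_numpy(dtype=float) if "w" in df else np.ones(len(df))
    xc = x - np.average(x, weights=w)
    r = w[:, None] * np.exp(np.outer(xc, beta))      # (n, G)
    ll = np.zeros(len(beta))
    for t in np.unique(stop[event]):
        at_risk = (start < t) & (t <= stop)
        dead = event & (stop == t)
        d = dead.sum()
        s0 = r[at_risk].sum(axis=0)
        sd0 = r[dead].sum(axis=0)
        wbar = w[dead].sum() / d
        ll += np.sum(w[dead] * xc[dead]) * beta
        for ell in range(d):
            frac = ell / d if ties == "efron" else 0.0
            ll -= wbar * np.log(s0 - frac * sd0)
    return ll if ll.size > 1 else float(ll[0])


def grid_search_beta(df, lo=-5.0, hi=5.0, step=1e-4, ties="efron"):
    grid = np.arange(lo, hi + step, step)
    lls = brute_force_cox_loglik(df, grid, ties)
    return float(grid[int(np.argmax(lls))])
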