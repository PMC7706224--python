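"""Synthetic longitudinal cohort generator.

Emulates the statistical structure a secular-trend / treatment-drop-in
analysis assumes: subjects enter uniformly over a calendar window, carry
mixed-type covariates that drift at 6-month steps, face a piecewise-constant
event hazard with a calendar-time trend, and may initiate a protective
treatment (statins) during follow-up at a rate that depends on their
*current* covariates and on calendar time — the confounded "drop-in"
structure.  Follow-up ends at the earliest of the event, random censoring,
or the administrative horizon (5 years by default).

Within each 6-month interval the hazards are constant (covariates and
calendar time frozen at the interval start), so event and initiation times
are drawn by inverse-CDF exponential sampling.  The generator consumes a
fixed number of random draws per subject-interval regardless of what
happens, so two scenarios differing only in their hazard parameters but
sharing a seed are draw-for-draw paired — this is what makes treated /
untreated counterfactual "paired world" comparisons exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import INTERVAL_YEARS, CovariateSpec, ScenarioConfig, ScenarioError


@dataclass
class SubjectPath:
    """One simulated subject (a convenience view onto :class:`Cohort`)."""

    subject_id: int
    entry_years: float
    entry_date: object
    covariates: dict            # name -> array of values at the 10 time points
    missing_mask: dict          # name -> bool array, True = masked
    initiation_time: float | None
    event_time: float | None
    censor_time: float

    def treatment_status(self, n_timepoints: int) -> np.ndarray:
        """A_k at each 6-month time point: 1 iff initiation strictly before k."""
        grid = np.arange(n_timepoints) * INTERVAL_YEARS
        if self.initiation_time is None:
            return np.zeros(n_timepoints, dtype=int)
        return (grid > self.initiation_time).astype(int)


@dataclass
class Cohort:
    """Vectorised container for a simulated cohort.

    ``values`` holds the *true* covariate paths, shape (n, K) per variable;
    ``mask`` marks entries hidden by :func:`apply_missingness` (the truth is
    retained so imputation can be checked against it).  Times are years
    from entry; ``event_time``/``initiation_time`` are NaN when absent.
    """

    config: ScenarioConfig
    entry_years: np.ndarray
    values: dict
    mask: dict
    initiation_time: np.ndarray
    event_time: np.ndarray
    censor_time: np.ndarray
    prior_statin: np.ndarray = None
    prior_event: np.ndarray = None
    ids: np.ndarray = None

    def __post_init__(self):
        n = len(self.entry_years)
        if self.ids is None:
            self.ids = np.arange(n)
        if self.prior_statin is None:
            self.prior_statin = np.zeros(n, dtype=bool)
        if self.prior_event is None:
            self.prior_event = np.zeros(n, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.entry_years)

    @property
    def n_timepoints(self) -> int:
        return self.config.n_timepoints

    def observed(self, name: str) -> np.ndarray:
        """Covariate path with masked entries as NaN."""
        out = self.values[name].astype(float).copy()
        out[self.mask[name]] = np.nan
        return out

    def subject(self, i: int) -> SubjectPath:
        init = self.initiation_time[i]
        ev = self.event_time[i]
        return SubjectPath(
            subject_id=int(self.ids[i]),
            entry_years=float(self.entry_years[i]),
            entry_date=self.config.years_to_date(float(self.entry_years[i])),
            covariates={k: v[i].copy() for k, v in self.values.items()},
            missing_mask={k: v[i].copy() for k, v in self.mask.items()},
            initiation_time=None if np.isnan(init) else float(init),
            event_time=None if np.isnan(ev) else float(ev),
            censor_time=float(self.censor_time[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per subject-timepoint, ISO dates, years from entry."""
        K, n = self.n_timepoints, self.n
        rep = np.repeat(np.arange(n), K)
        k = np.tile(np.arange(K), n)
        df = pd.DataFrame({
            "id": self.ids[rep],
            "k": k,
            "time": k * INTERVAL_YEARS,
            "entry_years": self.entry_years[rep],
            "entry_date": [str(self.config.years_to_date(t))
                           for t in self.entry_years[rep]],
            "initiation_time": self.initiation_time[rep],
            "event_time": self.event_time[rep],
            "censor_time": self.censor_time[rep],
        })
        for name in self.values:
            df[name] = self.values[name].reshape(-1)
            df[f"miss_{name}"] = self.mask[name].reshape(-1)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: ScenarioConfig) -> "Cohort":
        K = config.n_timepoints
        df = df.sort_values(["id", "k"], kind="stable")
        ids = df["id"].to_numpy()[::K]
        names = [c.name for c in config.covariates]
        values = {nm: df[nm].to_numpy().reshape(-1, K) for nm in names}
        mask = {nm: df[f"miss_{nm}"].to_numpy(dtype=bool).reshape(-1, K)
                for nm in names}
        per = df.iloc[::K]
        return cls(config=config,
                   entry_years=per["entry_years"].to_numpy(float),
                   values=values, mask=mask,
                   initiation_time=per["initiation_time"].to_numpy(float),
                   event_time=per["event_time"].to_numpy(float),
                   censor_time=per["censor_time"].to_numpy(float),
                   ids=ids.copy())


# ---------------------------------------------------------------------------
# covariate machinery

def _draw_baseline(cov: CovariateSpec, n: int, rng) -> np.ndarray:
    if cov.kind == "continuous":
        return rng.normal(cov.mean, cov.sd, size=n)
    if cov.kind == "binary":
        return (rng.random(n) < cov.p).astype(float)
    # categorical: level codes 0..L-1
    u = rng.random(n)
    cum = np.cumsum(cov.probs)
    return np.searchsorted(cum, u, side="right").astype(float)


def _effect_columns(cov: CovariateSpec, vals_k: np.ndarray, which: str) -> np.ndarray:
    """Log-hazard contribution of one covariate at one time point."""
    eff = getattr(cov, which)
    if cov.kind == "categorical":
        out = np.zeros_like(vals_k, dtype=float)
        for j, b in enumerate(eff, start=1):
            out += np.where(vals_k == j, float(b), 0.0)
        return out
    return float(eff) * (vals_k - cov.ref_value)


def _exp_time(u: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """Inverse-CDF exponential draw; rate 0 -> +inf (the event never happens)."""
    with np.errstate(divide="ignore"):
        return np.where(rate > 0, -np.log(u) / np.maximum(rate, 1e-300), np.inf)


# ---------------------------------------------------------------------------
# simulation

def simulate_cohort(config: ScenarioConfig, seed: int | None = None) -> Cohort:
    """Simulate a cohort under ``config``; fully reproducible from the seed.

    Entry dates are uniform on the calendar window.  Continuous covariates
    follow a Gaussian random walk across the half-year grid; binary and
    categorical covariates are fixed at their entry value.  Within each
    6-month interval the event hazard is

        h_event = baseline_event_hazard
                  * exp(sum_j beta_j (x_jk - ref_j)
                        + trend_outcome * calendar_years
                        + treatment_log_hr * A)

    and, while untreated, the initiation hazard is the analogous
    expression with the initiation coefficients.  Calendar time is frozen
    at the interval start, and A is the treatment status at the interval
    start: a statin prescribed during an interval starts protecting at the
    next 6-month point (treatment-onset lag matching the half-year review
    grid), which keeps the discrete A_k representation of exposure exact.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, K = int(config.n_subjects), config.n_timepoints

    entry = rng.uniform(0.0, config.window_years, size=n)

    values: dict[str, np.ndarray] = {}
    for cov in config.covariates:
        base = _draw_baseline(cov, n, rng)
        steps = rng.normal(0.0, 1.0, size=(n, K - 1)) if K > 1 else np.zeros((n, 0))
        path = np.empty((n, K))
        path[:, 0] = base
        if cov.kind == "continuous" and cov.drift_sd > 0:
            path[:, 1:] = base[:, None] + np.cumsum(cov.drift_sd * steps, axis=1)
        else:
            path[:, 1:] = base[:, None]
        values[cov.name] = path

    initiation = np.full(n, np.nan)
    event = np.full(n, np.nan)
    censor = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    treated = np.zeros(n, dtype=bool)
    half = INTERVAL_YEARS

    for k in range(K):
        u = rng.random((3, n))  # fixed draw count per interval: keeps worlds paired
        lp_out = np.zeros(n)
        lp_init = np.zeros(n)
        for cov in config.covariates:
            vk = values[cov.name][:, k]
            lp_out += _effect_columns(cov, vk, "outcome_log_hr")
            lp_init += _effect_columns(cov, vk, "initiation_log_hr")
        cal = entry + k * half
        r_ev = config.baseline_event_hazard * np.exp(
            lp_out + config.trend_outcome * cal
            + config.treatment_log_hr * treated)
        r_init = config.baseline_initiation_hazard * np.exp(
            lp_init + config.trend_initiation * cal)

        # treatment takes effect at the next 6-month point: an initiation
        # during this interval leaves the current event hazard unchanged,
        # so initiation and the event race independently within the interval
        t_init = _exp_time(u[0], np.where(treated, 0.0, r_init))
        t_ev = _exp_time(u[1], r_ev)
        t_cens = _exp_time(u[2], np.full(n, config.random_censor_hazard))

        t0 = k * half
        exit_t = np.minimum(t_ev, t_cens)
        init_here = active & ~treated & (t_init < np.minimum(exit_t, half))
        initiation[init_here] = t0 + t_init[init_here]
        treated[init_here] = True

        done = active & (exit_t < half)
        ev = done & (t_ev <= t_cens)
        event[ev] = t0 + t_ev[ev]
        ce = done & ~ev
        censor[ce] = t0 + t_cens[ce]
        active[done] = False

    censor[active] = config.admin_horizon
    # events get a nominal censor time at the horizon (the administrative
    # censoring they would otherwise have met)
    censor[~np.isnan(event)] = config.admin_horizon

    mask = {cov.name: np.zeros((n, K), dtype=bool) for cov in config.covariates}
    return Cohort(config=config, entry_years=entry, values=values, mask=mask,
                  initiation_time=initiation, event_time=event,
                  censor_time=censor)


def apply_missingness(cohort: Cohort, config: ScenarioConfig | None = None,
                      seed: int | None = None) -> Cohort:
    """Set the missingness masks in place (true values are retained).

    MCAR masks are independent of everything; ``mar_age`` masks with a
    probability that is logistic in the subject's current value of the
    age variable, with the intercept anchored at the requested marginal
    probability at the mean age.
    """
    from scipy.special import expit, logit

    config = cohort.config if config is None else config
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed,
                               spawn_key=(17,)))
    n, K = cohort.n, cohort.n_timepoints
    for name, ms in config.missingness.items():
        ms.validate(name)
        u = rng.random((n, K))
        if ms.prob <= 0.0:
            cohort.mask[name][:] = False
            continue
        if ms.prob >= 1.0:
            cohort.mask[name][:] = True
            continue
        if ms.mechanism == "mcar":
            p = np.full((n, K), ms.prob)
        else:  # mar_age
            if ms.age_var not in cohort.values:
                raise ScenarioError(
                    f"missingness[{name}].age_var: {ms.age_var!r} not simulated")
            age = cohort.values[ms.age_var]
            p = expit(logit(ms.prob) + ms.slope * (age - age.mean()))
        if ms.level == "subject":
            # never-measured pattern: one draw per subject masks the path
            cohort.mask[name][:] = (u[:, :1] < p[:, :1])
        else:
            cohort.mask[name][:] = u < p
    return cohort


def analytic_incidence(config: ScenarioConfig, t: float,
                       entry_years: float | np.ndarray = 0.0) -> np.ndarray | float:
    """Closed-form cumulative incidence for the covariate-free, untreated case.

    Integrates the piecewise-constant hazard the simulator actually uses
    (calendar time frozen at each half-year interval start):

        1 - exp( - sum_k  h0 * exp(gamma_T * (entry + k/2)) * len_k )

    Valid only when no covariate affects the outcome; raises otherwise.
    Serves as the independent oracle for the simulator's event process.
    """
    for cov in config.covariates:
        if np.any(np.asarray(cov.outcome_log_hr, dtype=float) != 0.0):
            raise ScenarioError(
                f"covariates[{cov.name}].outcome_log_hr: analytic_incidence "
                "requires all outcome effects to be zero")
    t = float(t)
    if t < 0:
        raise ScenarioError("t: must be >= 0")
    entry = np.asarray(entry_years, dtype=float)
    h0, g = config.baseline_event_hazard, config.trend_outcome
    n_steps = int(np.ceil(t / INTERVAL_YEARS))
    total = np.zeros_like(entry, dtype=float)
    for k in range(n_steps):
        seg = min(INTERVAL_YEARS, t - k * INTERVAL_YEARS)
        total += h0 * np.exp(g * (entry + k * INTERVAL_YEARS)) * seg
    out = 1.0 - np.exp(-total)
    return float(out) if np.ndim(entry_years) == 0 else out
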