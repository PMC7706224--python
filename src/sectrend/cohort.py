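"""Cohort derivation: eligibility, censoring, calendar split, interval table.

Implements the primary-prevention cohort rules on simulated subjects —
exclusion of anyone with a pre-entry event or statin prescription,
truncation of follow-up at five years / study end, the development vs
validation split at a calendar cut date with administrative censoring at
the cut — and the construction of the counting-process interval table
(one row per subject per 6-month interval at risk) that all longitudinal
fits consume.

Treatment timing convention: ``treat`` (A_k) is 1 on an interval iff the
statin initiation happened *strictly before* the interval start, so the
initiation interval itself still counts as untreated person-time.  An
initiation followed by the event within 6 months is discarded entirely
(reverse-causation guard: the prescription may have been triggered by the
impending event), leaving that subject untreated throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import INTERVAL_YEARS
from .simulate import Cohort

log = logging.getLogger(__name__)


class DataIntegrityError(ValueError):
    pass


def derive_baseline_cohort(cohort: Cohort, study_end_years: float | None = None,
                           values: dict | None = None) -> pd.DataFrame:
    """Apply eligibility and censoring rules; one row per eligible subject.

    Excludes subjects flagged with a pre-entry event or statin
    prescription.  Follow-up is the earliest of the subject's censoring
    time, the study end, and the administrative horizon; the event
    indicator is set only if the event falls within follow-up.

    ``values`` optionally supplies covariate paths (e.g. after
    imputation); by default the observed (masked-to-NaN) paths are used
    for the baseline ``x0_`` columns.
    """
    if np.any(np.nan_to_num(cohort.event_time, nan=0.0) < 0):
        raise DataIntegrityError("negative event_time encountered")
    keep = ~(cohort.prior_statin | cohort.prior_event)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("excluded %d subjects with pre-entry event/statin", n_drop)

    entry = cohort.entry_years[keep]
    censor = cohort.censor_time[keep].copy()
    exit_cens = np.minimum(censor, cohort.config.admin_horizon)
    if study_end_years is not None:
        exit_cens = np.minimum(exit_cens, study_end_years - entry)
    ev = cohort.event_time[keep]
    has_event = ~np.isnan(ev) & (ev <= exit_cens)
    follow = np.where(has_event, ev, exit_cens)

    pos = follow > 0
    if int((~pos).sum()):
        log.info("dropped %d subjects with no follow-up inside the study window",
                 int((~pos).sum()))

    idx = np.flatnonzero(keep)[pos]
    df = pd.DataFrame({
        "id": cohort.ids[idx],
        "t0": cohort.entry_years[idx],
        "follow": follow[pos],
        "event": has_event[pos].astype(int),
    })
    src = values if values is not None else {
        name: cohort.observed(name) for name in cohort.values}
    for name, path in src.items():
        df[f"x0_{name}"] = path[idx, 0]
    return df.reset_index(drop=True)


def split_by_cut_date(baseline: pd.DataFrame, cut_years: float,
                      window_years: float | None = None) -> tuple:
    """Split at the calendar cut; development follow-up is censored there.

    Entry strictly before the cut puts a subject in the development
    cohort, with follow-up administratively censored at the cut (an event
    on or after the cut does not count; the boundary is exclusive).
    Entry on/after the cut puts them, untouched, in the validation cohort.
    """
    if cut_years <= 0 or (window_years is not None and cut_years > window_years):
        raise ValueError("cut_date falls outside the study window")
    is_dev = baseline["t0"].to_numpy() < cut_years
    dev = baseline[is_dev].copy()
    val = baseline[~is_dev].copy()

    rem = cut_years - dev["t0"].to_numpy()
    follow = dev["follow"].to_numpy()
    event = dev["event"].to_numpy().astype(bool)
    # event counts only if strictly before the cut
    new_event = event & (dev["t0"].to_numpy() + follow < cut_years)
    new_follow = np.minimum(follow, rem)
    dev["follow"], dev["event"] = new_follow, new_event.astype(int)
    zero = dev["follow"].to_numpy() <= 0
    if int(zero.sum()):
        log.info("dropped %d development subjects with no follow-up before the cut",
                 int(zero.sum()))
        dev = dev[~zero]
    dev["cohort_label"] = "development"
    val["cohort_label"] = "validation"
    return dev.reset_index(drop=True), val.reset_index(drop=True)


def effective_initiation(cohort: Cohort, baseline: pd.DataFrame,
                         near_event_rule: bool = True) -> pd.Series:
    """Initiation time per subject, optionally after the near-event rule.

    With ``near_event_rule`` (the default), an initiation followed by the
    observed event within 6 months is ignored (NaN) and the subject counts
    as never treated — the reverse-causation guard for observational data,
    where the prescription may have been triggered by the impending event.
    On simulated data, where no such recording artefact exists, the guard
    selectively deletes genuine early-treatment events and makes treatment
    look more protective than it is; causal-recovery analyses on synthetic
    cohorts should disable it.  Initiations after the end of observed
    follow-up are always NaN.
    """
    pos = pd.Series(np.arange(cohort.n), index=cohort.ids)
    rows = pos[baseline["id"].to_numpy()].to_numpy()
    init = cohort.initiation_time[rows].copy()
    follow = baseline["follow"].to_numpy(dtype=float)
    event = baseline["event"].to_numpy(dtype=bool)
    with np.errstate(invalid="ignore"):
        init[init > follow] = np.nan
        if near_event_rule:
            near = event & ~np.isnan(init) & (follow - init < INTERVAL_YEARS)
            init[near] = np.nan
    return pd.Series(init, index=baseline["id"].to_numpy(), name="initiation")


def build_interval_table(baseline: pd.DataFrame, cohort: Cohort,
                         filled_values: dict,
                         init_times: pd.Series | None = None) -> pd.DataFrame:
    """Counting-process rows at the half-year grid for every subject.

    One row per subject per 6-month interval at risk; the final row stops
    at the subject's exit and carries the event flag.  ``filled_values``
    must be fully imputed covariate paths (name -> (n, K) array aligned to
    ``cohort``); a remaining NaN at any used time point is an error.

    Columns: ``id, k, start, stop, event, treat, t0_years``, baseline
    covariates as ``x0_<name>`` and time-varying ones as ``xk_<name>``.
    """
    if init_times is None:
        init_times = effective_initiation(cohort, baseline)
    pos = pd.Series(np.arange(cohort.n), index=cohort.ids)
    rows = pos[baseline["id"].to_numpy()].to_numpy()
    follow = baseline["follow"].to_numpy(dtype=float)
    event = baseline["event"].to_numpy(dtype=bool)
    init = init_times.to_numpy(dtype=float)

    lengths = np.ceil(follow / INTERVAL_YEARS - 1e-12).astype(int)
    rep = np.repeat(np.arange(len(baseline)), lengths)
    k = np.concatenate([np.arange(L) for L in lengths]) if len(baseline) else \
        np.empty(0, dtype=int)
    start = k * INTERVAL_YEARS
    stop = np.minimum(start + INTERVAL_YEARS, follow[rep])
    last = k == (lengths[rep] - 1)
    ev = (last & event[rep]).astype(int)
    with np.errstate(invalid="ignore"):
        treat = (~np.isnan(init[rep]) & (init[rep] < start)).astype(int)

    out = pd.DataFrame({
        "id": baseline["id"].to_numpy()[rep],
        "k": k,
        "start": start,
        "stop": stop,
        "event": ev,
        "treat": treat,
        "t0_years": baseline["t0"].to_numpy()[rep],
    })
    for name, path in filled_values.items():
        vals = path[rows[rep], k]
        if np.any(np.isnan(vals)):
            raise DataIntegrityError(
                f"covariate {name!r} still missing at a used time point; "
                "run the imputation cascade first")
        out[f"xk_{name}"] = vals
        out[f"x0_{name}"] = path[rows[rep], 0]
    return out
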