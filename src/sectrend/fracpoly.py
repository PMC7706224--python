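"""Fractional polynomials (FP) for continuous predictors.

A first-degree FP transforms a positive variable v as v^p for one power p
from {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (p = 0 meaning log v); a
second-degree FP uses an ordered pair of powers, with the repeated pair
(p, p) giving (v^p, v^p log v).  Variables are shifted to positivity and
scaled by a power of ten before transformation, Royston-style.

:func:`select_fp` runs the closed test procedure under a Cox partial
likelihood: best FP2 against the null (4 df), against linear (3 df), and
against the best FP1 (2 df), each at level alpha, returning the simplest
form not rejected.  Selected specs are frozen and reused verbatim in
downstream (including weighted) fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats

from .survival import ConvergenceError, CoxError, fit_cox

POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class FPError(ValueError):
    pass


@dataclass(frozen=True)
class FPSpec:
    """A frozen fractional-polynomial transform for one variable.

    ``powers`` is empty (variable dropped), length 1 (FP1), or an ordered
    pair (FP2).  ``shift`` is added and ``scale`` divides before the
    powers are applied; the shifted-scaled values must be positive.
    """

    name: str
    powers: tuple
    shift: float = 0.0
    scale: float = 1.0

    def column_names(self) -> list[str]:
        return [f"{self.name}_fp{i + 1}" for i in range(len(self.powers))]

    def transform(self, x) -> np.ndarray:
        return fp_transform(x, self)


def _basis(v: np.ndarray, powers) -> np.ndarray:
    cols = []
    prev_p, prev_col = None, None
    for p in powers:
        col = np.log(v) if p == 0 else v ** p
        if prev_p is not None and p == prev_p:
            col = prev_col * np.log(v)     # repeated power: v^p log v
        cols.append(col)
        prev_p, prev_col = p, col
    return np.column_stack(cols) if cols else np.empty((len(v), 0))


def fp_transform(x, spec: FPSpec) -> np.ndarray:
    """Design columns of ``x`` under ``spec`` (deterministic, vectorised)."""
    x = np.asarray(x, dtype=float)
    v = (x + spec.shift) / spec.scale
    if np.any(v <= 0):
        bad = np.asarray(x)[v <= 0][:5]
        raise FPError(
            f"{spec.name}: nonpositive values after shift/scale, e.g. {bad}")
    return _basis(v, spec.powers)


def auto_shift_scale(x) -> tuple[float, float]:
    """Royston-style shift to positivity and power-of-ten scaling."""
    x = np.asarray(x, dtype=float)
    xmin = float(np.min(x))
    shift = 0.0
    if xmin <= 0:
        diffs = np.diff(np.unique(x))
        inc = float(diffs.min()) if len(diffs) else 1.0
        shift = -xmin + inc
    spread = float(np.max(x) + shift)
    scale = 10.0 ** np.floor(np.log10(spread)) if spread > 0 else 1.0
    return shift, max(scale, 1e-12)


def _candidate_loglik(df, fp_cols, adjust, start, stop, event, weight):
    fit = fit_cox(df, list(fp_cols) + list(adjust), start=start, stop=stop,
                  event=event, weight=weight, compute_baseline=False,
                  robust=False)
    return fit.loglik


def select_fp(df: pd.DataFrame, variable: str, adjust=(), start="start",
              stop="stop", event="event", weight=None, alpha: float = 0.05,
              shift: float | None = None, scale: float | None = None) -> FPSpec:
    """Closed-test FP selection for ``variable`` under a Cox model.

    Fits every FP1 and FP2 candidate (with fixed adjustment covariates)
    and applies the function-selection procedure: if the best FP2 does not
    beat the null at ``alpha`` (chi-square, 4 df) the variable is dropped;
    if it does not beat linear (3 df) the linear form is kept; if it does
    not beat the best FP1 (2 df) the best FP1 is kept; otherwise the best
    FP2 wins.  Non-convergent candidates are skipped with a warning.
    """
    x = df[variable].to_numpy(dtype=float)
    auto = auto_shift_scale(x)
    shift = auto[0] if shift is None else shift
    scale = auto[1] if scale is None else scale
    work = df.copy()

    def loglik_for(powers):
        spec = FPSpec(variable, tuple(powers), shift, scale)
        cols = spec.column_names()
        basis = spec.transform(x)
        for j, c in enumerate(cols):
            work[c] = basis[:, j]
        try:
            return _candidate_loglik(work, cols, adjust, start, stop, event,
                                     weight)
        except (ConvergenceError, CoxError) as exc:
            warnings.warn(f"FP candidate {powers} for {variable!r} skipped: {exc}",
                          RuntimeWarning)
            return None

    # null: adjusters only (or the empty model)
    if adjust:
        ll_null = _candidate_loglik(work, [], adjust, start, stop, event, weight)
    else:
        fit0 = fit_cox(work, [], start=start, stop=stop, event=event,
                       weight=weight, compute_baseline=False, robust=False)
        ll_null = fit0.loglik

    fp1 = {(p,): loglik_for((p,)) for p in POWERS}
    fp2 = {pair: loglik_for(pair)
           for pair in combinations_with_replacement(POWERS, 2)}
    fp1 = {k: v for k, v in fp1.items() if v is not None}
    fp2 = {k: v for k, v in fp2.items() if v is not None}
    if not fp1 or not fp2:
        raise FPError(f"all FP candidate fits failed for {variable!r}")

    best1 = max(fp1, key=fp1.get)
    best2 = max(fp2, key=fp2.get)
    ll_lin = fp1.get((1.0,))
    if ll_lin is None:
        raise FPError(f"linear candidate failed for {variable!r}")

    def pval(ll_big, ll_small, dof):
        return stats.chi2.sf(max(2.0 * (ll_big - ll_small), 0.0), dof)

    if pval(fp2[best2], ll_null, 4) > alpha:
        return FPSpec(variable, (), shift, scale)
    if pval(fp2[best2], ll_lin, 3) > alpha:
        return FPSpec(variable, (1.0,), shift, scale)
    if pval(fp2[best2], fp1[best1], 2) > alpha:
        return FPSpec(variable, best1, shift, scale)
    return FPSpec(variable, best2, shift, scale)
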