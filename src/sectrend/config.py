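"""Scenario and study configuration.

A :class:`ScenarioConfig` holds every data-generating parameter of a
synthetic primary-prevention cohort: the calendar window, the baseline
covariate distributions and their log hazard ratios on the outcome and on
treatment (statin) initiation, the calendar-time trends in both hazards,
the causal treatment effect, censoring, and missingness.  A
:class:`StudyConfig` holds the analysis-side choices (development /
validation cut date, which continuous variables get fractional-polynomial
selection, calibration group count, weight truncation).

Calendar time is measured in years since the start of the calendar window;
ISO dates are converted with a 365.25-day year.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import yaml

DAYS_PER_YEAR = 365.25

#: half-year spacing of the longitudinal extraction grid
INTERVAL_YEARS = 0.5


class ScenarioError(ValueError):
    """Raised when a configuration field fails validation; names the field."""


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ScenarioError(f"{fieldname}: {msg}")


def parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def years_between(start, end) -> float:
    """Elapsed years (365.25-day) from ``start`` to ``end``."""
    return (parse_date(end) - parse_date(start)).days / DAYS_PER_YEAR


@dataclass
class MissingSpec:
    """Per-variable missingness mechanism.

    prob
        Marginal masking probability in [0, 1].
    mechanism
        ``"mcar"`` (independent of everything) or ``"mar_age"`` (masking
        probability a logistic function of the subject's current value of
        ``age_var``, centred so the marginal rate stays close to ``prob``).
    level
        ``"entry"`` masks each subject-timepoint independently (sporadic
        gaps, later closed by LOCF/NOCB); ``"subject"`` masks a variable at
        *all* time points for the selected subjects — the never-measured
        pattern that only the stochastic baseline imputation can fill.
    slope
        Log-odds change in masking probability per unit of the age
        variable (``mar_age`` only).
    """

    prob: float
    mechanism: str = "mcar"
    level: str = "entry"
    age_var: str = "age"
    slope: float = 0.05

    def validate(self, name: str) -> None:
        _require(0.0 <= self.prob <= 1.0, f"missingness[{name}].prob",
                 "must be in [0, 1]")
        if self.mechanism not in ("mcar", "mar_age"):
            raise ScenarioError(
                f"missingness[{name}].mechanism: unknown mechanism "
                f"{self.mechanism!r} (expected 'mcar' or 'mar_age')")
        if self.level not in ("entry", "subject"):
            raise ScenarioError(
                f"missingness[{name}].level: unknown level {self.level!r}")


@dataclass
class CovariateSpec:
    """One baseline covariate of the synthetic cohort.

    Continuous covariates are Gaussian at entry and follow a Gaussian
    random walk (sd ``drift_sd`` per 6-month step).  Binary and
    categorical covariates are drawn at entry and held fixed.  Effects are
    additive on the log hazard scale, applied to ``x - reference`` for
    continuous variables (``reference`` defaults to the mean) so that the
    scenario's baseline hazards describe a reference subject.
    """

    name: str
    kind: str = "continuous"
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5
    levels: tuple = ()
    probs: tuple = ()
    outcome_log_hr: object = 0.0   # float, or sequence per non-reference level
    initiation_log_hr: object = 0.0
    drift_sd: float = 0.0
    reference: float | None = None

    def validate(self) -> None:
        f = f"covariates[{self.name}]"
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ScenarioError(f"{f}.kind: unknown kind {self.kind!r}")
        if self.kind == "continuous":
            _require(self.sd >= 0, f"{f}.sd", "must be >= 0")
            _require(self.drift_sd >= 0, f"{f}.drift_sd", "must be >= 0")
        elif self.kind == "binary":
            _require(0.0 <= self.p <= 1.0, f"{f}.p", "must be in [0, 1]")
        else:
            _require(len(self.levels) >= 2, f"{f}.levels",
                     "categorical needs >= 2 levels")
            _require(len(self.probs) == len(self.levels), f"{f}.probs",
                     "must match levels")
            _require(abs(sum(self.probs) - 1.0) < 1e-8, f"{f}.probs",
                     "must sum to 1")
            for eff in ("outcome_log_hr", "initiation_log_hr"):
                v = getattr(self, eff)
                if np.ndim(v) == 0:
                    v = [float(v)] * (len(self.levels) - 1)
                    setattr(self, eff, tuple(v))
                _require(len(v) == len(self.levels) - 1, f"{f}.{eff}",
                         "needs one effect per non-reference level")

    @property
    def ref_value(self) -> float:
        if self.kind == "continuous":
            return self.mean if self.reference is None else self.reference
        if self.kind == "binary":
            return self.p
        return 0.0

    def design_names(self) -> list[str]:
        """Column names this covariate contributes to a design matrix."""
        if self.kind == "categorical":
            return [f"{self.name}_{lv}" for lv in self.levels[1:]]
        return [self.name]


@dataclass
class ScenarioConfig:
    """All data-generating parameters for one synthetic cohort."""

    n_subjects: int
    calendar_window: tuple = ("1998-01-01", "2015-12-31")
    covariates: list = field(default_factory=list)
    baseline_event_hazard: float = 0.01     # events / person-year, reference subject
    trend_outcome: float = 0.0              # per-year change in log event hazard
    baseline_initiation_hazard: float = 0.0  # initiations / person-year
    trend_initiation: float = 0.0           # per-year change in log initiation hazard
    treatment_log_hr: float = 0.0           # causal statin effect on events
    random_censor_hazard: float = 0.0       # per person-year
    admin_horizon: float = 5.0              # years
    missingness: dict = field(default_factory=dict)  # name -> MissingSpec
    seed: int = 0

    def __post_init__(self):
        self.covariates = [
            c if isinstance(c, CovariateSpec) else CovariateSpec(**c)
            for c in self.covariates
        ]
        self.missingness = {
            k: (v if isinstance(v, MissingSpec) else MissingSpec(**v))
            for k, v in self.missingness.items()
        }
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        _require(int(self.n_subjects) >= 0, "n_subjects", "must be >= 0")
        start, end = (parse_date(d) for d in self.calendar_window)
        _require(start < end, "calendar_window", "start_date must precede end_date")
        for f in ("baseline_event_hazard", "baseline_initiation_hazard",
                  "random_censor_hazard"):
            v = float(getattr(self, f))
            _require(np.isfinite(v) and v >= 0.0, f, "must be a finite rate >= 0")
        _require(self.admin_horizon > 0, "admin_horizon", "must be > 0")
        for f in ("trend_outcome", "trend_initiation", "treatment_log_hr"):
            _require(np.isfinite(float(getattr(self, f))), f, "must be finite")
        names = [c.name for c in self.covariates]
        _require(len(names) == len(set(names)), "covariates", "duplicate names")
        for c in self.covariates:
            c.validate()
        for name, ms in self.missingness.items():
            _require(name in names, f"missingness[{name}]",
                     "refers to an unknown covariate")
            ms.validate(name)

    # -- derived quantities ---------------------------------------------
    @property
    def window_start(self) -> dt.date:
        return parse_date(self.calendar_window[0])

    @property
    def window_years(self) -> float:
        return years_between(*self.calendar_window)

    @property
    def n_timepoints(self) -> int:
        """Number of 6-month extraction time points (10 for a 5-year horizon)."""
        return int(round(self.admin_horizon / INTERVAL_YEARS))

    def date_to_years(self, date) -> float:
        return years_between(self.window_start, date)

    def years_to_date(self, years: float) -> dt.date:
        return self.window_start + dt.timedelta(days=round(years * DAYS_PER_YEAR))

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["calendar_window"] = [str(x) for x in self.calendar_window]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"scenario": self.to_dict()}, fh, sort_keys=False)


@dataclass
class StudyConfig:
    """Analysis-side configuration of the end-to-end study."""

    cut_date: str = "2010-01-01"
    fp_variables: tuple = ()        # continuous covariates tested for FPs
    calendar_fp: bool = True        # FP-select calendar time in the trend model
    n_groups: int = 10              # calibration risk groups
    fp_alpha: float = 0.05
    weight_truncation: tuple | None = None  # e.g. (1, 99) percentiles
    weight_model_full_fp: bool = False  # keep 2nd-order FP terms in weight models
    horizon: float = 5.0

    def validate(self, scenario: ScenarioConfig) -> None:
        cut = scenario.date_to_years(self.cut_date)
        _require(0.0 < cut < scenario.window_years, "cut_date",
                 "must fall inside the calendar window")
        _require(cut >= self.horizon, "cut_date",
                 "development window must span the prediction horizon")
        _require(self.n_groups >= 1, "n_groups", "must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> tuple[ScenarioConfig, StudyConfig]:
    """Load a YAML file with top-level ``scenario:`` and optional ``study:``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    scenario = ScenarioConfig.from_dict(raw["scenario"])
    study = StudyConfig(**raw.get("study", {}))
    study.validate(scenario)
    return scenario, study


def save_config(path, scenario: ScenarioConfig, study: StudyConfig | None = None) -> None:
    payload = {"scenario": scenario.to_dict()}
    if study is not None:
        payload["study"] = study.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent generator for pipeline stage ``stage`` of run ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed) % 2**31,
                                                        spawn_key=(stage,)))
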