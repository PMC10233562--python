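"""Synthetic NSCLC-like cohort generator.

No patient-level data are distributed with this package; every other
module is exercised on cohorts drawn from this generator, whose defaults
emulate the summary profile of a late-stage NSCLC registry cohort:
n = 1423, roughly 2:1 male and adenocarcinoma predominance, stage
distribution skewed to III/IV (482 and 595 patients), median age 62
(IQR 52-67), ~47.4% deaths, and median observed follow-up ~499 days.

Mechanism
---------
* Clinical covariates are drawn independently (stage/sex/pathotype/
  smoking categorical; age from a piecewise-linear quantile curve hitting
  the target median and IQR).
* Base analytes are log-normal with 95% of their mass inside the adult
  reference interval.  Covariate effects shift the log-mean by a stated
  number of log-SDs per covariate level (stage is centered at 2.5 so the
  marginal stays anchored); correlation between analytes arises only
  through shared covariate effects.
* Differential cell counts are kept internally coherent: WBC is the sum
  of the five differentials, Gran = Neu + Eosin + Baso, the percentage
  analytes are count/WBC, and plateletcrit is Plt x MPV.  Effects can
  target any directly generated analyte, not these derived ones.
* Survival times follow a Weibull proportional-hazards model (shape
  1.2) with a log-hazard coefficient on stage; censoring is a uniform
  window blending staggered administrative entry with loss to follow-up,
  tuned together with the baseline scale so that the default event
  fraction is ~0.474 and median observed follow-up ~499 days.

The smoking prevalence default keeps the source count of 51/1423
(~3.6%) rather than the contradictory "approximately 36%" phrasing that
accompanies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .compute import LabPanel
from .survival import SurvivalRecord
from .units import ReferenceIntervals, default_reference_intervals

__all__ = ["EffectSpec", "CohortSpec", "generate_cohort", "inject_effect"]

_STAGES = ("I", "II", "III", "IV")
_STAGE_CODE = {"I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0}

# analytes drawn directly from log-normal marginals; the rest are derived
_BASE_ANALYTES = (
    "Neu", "Lymph", "Mono", "Eosin", "Baso",
    "RBC", "HGB", "MCHC", "Plt", "MPV", "PDW", "RDW",
    "Alb", "Glb", "preAlb", "CRP", "SAA", "Fib", "Ddim",
    "AST", "ALT", "ALP", "GGT", "LDH", "TBil", "Crea", "UA",
    "Glc", "TChol", "TG", "HDLC", "INR",
)

_COVARIATES = ("sex", "age", "smoking", "pathotype", "stage")


@dataclass(frozen=True)
class EffectSpec:
    """A covariate-linked shift of one analyte's log-mean.

    ``shift`` is in units of the analyte's log-SD per covariate level:
    stage contributes (stage - 2.5) levels, binary covariates 0/1
    (sex male=1, smoking ever=1, pathotype squamous=1), age its z-score.
    """

    analyte: str
    covariate: str
    shift: float

    def __post_init__(self) -> None:
        if self.covariate not in _COVARIATES:
            raise ValueError(f"unknown covariate {self.covariate!r}")


@dataclass(frozen=True)
class CohortSpec:
    n: int = 1423
    # III/IV counts are the stated 482/595; the I/II split is free and is
    # chosen so the matched screening subgroups (stage II heavy) stay feasible
    stage_probs: tuple[float, float, float, float] = (150 / 1423, 196 / 1423, 482 / 1423, 595 / 1423)
    male_fraction: float = 945 / 1423
    # P(adenocarcinoma | sex): women with NSCLC are predominantly
    # adenocarcinoma; the mix reproduces the overall 945/1423 fraction
    adenocarcinoma_by_sex: tuple[float, float] = (0.545, 0.90)  # (male, female)
    smoking_fraction: float = 51 / 1423
    # age inverse-CDF knots (quantile, years): median 62, IQR 52-67
    age_quantiles: tuple[tuple[float, float], ...] = (
        (0.0, 28.0),
        (0.25, 52.0),
        (0.5, 62.0),
        (0.75, 67.0),
        (1.0, 84.0),
    )
    effects: tuple[EffectSpec, ...] = (
        EffectSpec("GGT", "stage", 0.35),
        EffectSpec("Lymph", "stage", -0.30),
        EffectSpec("Neu", "stage", 0.20),
    )
    # Weibull proportional-hazards survival with uniform censoring window
    weibull_shape: float = 1.2
    weibull_scale: float = 1470.0  # days; tuned with the censoring window
    log_hr_stage: float = 0.5  # per stage level, centered at 2.5
    analyte_log_hr: tuple[tuple[str, float], ...] = ()
    censor_window: tuple[float, float] = (60.0, 1700.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise ValueError("stage probabilities must sum to 1")
        fractions = (self.male_fraction, self.smoking_fraction) + self.adenocarcinoma_by_sex
        for frac in fractions:
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for eff in self.effects:
            if eff.analyte not in _BASE_ANALYTES:
                raise ValueError(
                    f"effect targets {eff.analyte!r}, which is not a directly "
                    f"generated analyte (derived quantities cannot be shifted)"
                )
        for analyte, _ in self.analyte_log_hr:
            if analyte not in _BASE_ANALYTES:
                raise ValueError(f"survival coefficient on unknown analyte {analyte!r}")
        lo, hi = self.censor_window
        if not 0 < lo < hi:
            raise ValueError("censor window must satisfy 0 < low < high")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull parameters must be positive")
        qs = [q for q, _ in self.age_quantiles]
        if qs != sorted(qs) or qs[0] != 0.0 or qs[-1] != 1.0:
            raise ValueError("age quantile knots must span [0, 1] in order")


def _lognormal_params(interval) -> tuple[float, float]:
    """log-mean and log-SD placing 95% of mass inside the interval."""
    lo, hi = interval.lower, interval.upper
    if lo is None or hi is None or lo <= 0:
        raise ValueError(f"{interval.analyte}: need a positive two-sided interval")
    mu = 0.5 * (np.log(lo) + np.log(hi))
    sigma = (np.log(hi) - np.log(lo)) / (2 * 1.959963984540054)
    return mu, sigma


def _covariate_level(covariate: str, clinical: dict[str, np.ndarray]) -> np.ndarray:
    if covariate == "stage":
        return clinical["stage_code"] - 2.5
    if covariate == "sex":
        return clinical["sex_code"]
    if covariate == "smoking":
        return clinical["smoking_code"]
    if covariate == "pathotype":
        return clinical["pathotype_code"]
    age = clinical["age"]
    return (age - age.mean()) / max(age.std(), 1e-9)


def generate_cohort(
    spec: CohortSpec,
    intervals: ReferenceIntervals | None = None,
) -> tuple[list[LabPanel], list[SurvivalRecord]]:
    """Draw a cohort of lab panels and survival records.

    Reproducible: the same spec (including seed) yields identical output.
    """
    spec.validate()
    intervals = intervals or default_reference_intervals()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    stage_idx = rng.choice(4, size=n, p=spec.stage_probs)
    stage = np.array(_STAGES)[stage_idx]
    sex_code = (rng.random(n) < spec.male_fraction).astype(float)
    p_adeno = np.where(sex_code == 1.0, *spec.adenocarcinoma_by_sex)
    clinical = {
        "stage_code": stage_idx + 1.0,
        "sex_code": sex_code,
        "smoking_code": (rng.random(n) < spec.smoking_fraction).astype(float),
        "pathotype_code": (rng.random(n) >= p_adeno).astype(float),
    }
    qs, ys = zip(*spec.age_quantiles)
    clinical["age"] = np.round(np.interp(rng.random(n), qs, ys), 1)

    # per-analyte log-normal draws with covariate shifts on the log-mean
    shifts: dict[str, np.ndarray] = {a: np.zeros(n) for a in _BASE_ANALYTES}
    sigmas: dict[str, float] = {}
    values: dict[str, np.ndarray] = {}
    for eff in spec.effects:
        level = _covariate_level(eff.covariate, clinical)
        interval = intervals.get(eff.analyte)
        _, sigma = _lognormal_params(interval)
        shifts[eff.analyte] = shifts[eff.analyte] + eff.shift * sigma * level
    for analyte in _BASE_ANALYTES:
        mu, sigma = _lognormal_params(intervals.get(analyte))
        sigmas[analyte] = sigma
        values[analyte] = np.exp(mu + shifts[analyte] + sigma * rng.standard_normal(n))

    # coherent derived quantities
    wbc = values["Neu"] + values["Lymph"] + values["Mono"] + values["Eosin"] + values["Baso"]
    gran = values["Neu"] + values["Eosin"] + values["Baso"]
    derived = {
        "WBC": wbc,
        "Gran": gran,
        "Neu_ratio": values["Neu"] / wbc,
        "Lymph_ratio": values["Lymph"] / wbc,
        "Mono_ratio": values["Mono"] / wbc,
        "Baso_ratio": values["Baso"] / wbc,
        "PCT": values["Plt"] * values["MPV"] * 1e-4,  # %: (10^9/L x fL) scaled
    }

    # anthropometrics by sex
    male = clinical["sex_code"] == 1.0
    height = np.where(
        male,
        rng.normal(1.72, 0.06, size=n),
        rng.normal(1.60, 0.055, size=n),
    )
    bmi = np.exp(rng.normal(np.log(22.5), 0.12, size=n))
    weight = bmi * height**2

    # Weibull PH survival with uniform censoring
    lp = spec.log_hr_stage * (clinical["stage_code"] - 2.5)
    for analyte, coef in spec.analyte_log_hr:
        z = (np.log(values[analyte]) - np.log(values[analyte]).mean()) / sigmas[analyte]
        lp = lp + coef * z
    u = rng.random(n)
    event_time = spec.weibull_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / spec.weibull_shape)
    censor_time = rng.uniform(*spec.censor_window, size=n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    observed = np.maximum(np.round(observed), 1.0)  # whole days, minimum 1

    panels: list[LabPanel] = []
    records: list[SurvivalRecord] = []
    sex_label = np.where(male, "male", "female")
    smoking_label = np.where(clinical["smoking_code"] == 1.0, "ever", "never")
    pathotype_label = np.where(
        clinical["pathotype_code"] == 1.0, "squamous", "adenocarcinoma"
    )
    width = len(str(n))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        measurements: dict[str, tuple[float, str]] = {}
        for analyte in _BASE_ANALYTES:
            measurements[analyte] = (float(values[analyte][i]), "canonical")
        for analyte, arr in derived.items():
            measurements[analyte] = (float(arr[i]), "canonical")
        measurements["Height"] = (float(height[i]), "m")
        measurements["Weight"] = (float(weight[i]), "kg")
        measurements = {
            code: (v, _canonical_unit(code) if unit == "canonical" else unit)
            for code, (v, unit) in measurements.items()
        }
        panels.append(
            LabPanel(
                patient_id=pid,
                measurements=measurements,
                clinical={
                    "age": float(clinical["age"][i]),
                    "sex": str(sex_label[i]),
                    "smoking": str(smoking_label[i]),
                    "stage": str(stage[i]),
                    "pathotype": str(pathotype_label[i]),
                },
            )
        )
        records.append(SurvivalRecord(pid, float(observed[i]), int(event[i])))
    return panels, records


_CANONICAL_UNITS: dict[str, str] | None = None


def _canonical_unit(code: str) -> str:
    global _CANONICAL_UNITS
    if _CANONICAL_UNITS is None:
        from .units import default_unit_registry

        units = default_unit_registry()
        _CANONICAL_UNITS = {a: units.canonical_unit(a) for a in units.analytes}
    return _CANONICAL_UNITS[code]


def inject_effect(spec: CohortSpec, analyte: str, covariate: str, shift: float) -> CohortSpec:
    """Return a spec with an additional covariate-linked analyte shift."""
    eff = EffectSpec(analyte, covariate, shift)
    new = replace(spec, effects=spec.effects + (eff,))
    new.validate()
    return new


def true_survival_probability(
    spec: CohortSpec, stage: Sequence[str] | np.ndarray, horizon: float
) -> np.ndarray:
    """Model survival probability at a horizon for given stages.

    S(t | stage) = exp(-(t/scale)^shape * exp(lp)) under the generator's
    Weibull proportional-hazards mechanism (no analyte effects).
    """
    code = np.array([_STAGE_CODE[s] for s in np.asarray(stage)])
    lp = spec.log_hr_stage * (code - 2.5)
    base = (horizon / spec.weibull_scale) ** spec.weibull_shape
    return np.exp(-base * np.exp(lp))
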