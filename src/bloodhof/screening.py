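"""Correlation screening of blood features against clinical covariates.

The procedure: build a matched subgroup in which every clinical
covariate except the target is held fixed (or quota-balanced), compute
the Spearman rank correlation of each blood feature against the target
covariate, and keep features whose |rho| exceeds a fixed threshold
chosen by group size (0.305 at n=60; 0.321 at n=52 for the smoking
group).  No multiplicity correction is applied — the design relies on
the fixed threshold alone.

Covariate encodings (configurable): sex male=1/female=0; smoking
ever=1/never=0; stage I..IV -> 1..4; pathotype adenocarcinoma=0/
squamous=1.  Missing feature cells are dropped pairwise per feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .compute import FeatureMatrix, LabPanel

__all__ = [
    "ScreeningGroup",
    "ScreeningConfig",
    "COVARIATE_CODES",
    "clinical_frame",
    "encode_covariate",
    "spearman_rho",
    "critical_rho",
    "build_group",
    "screen_features",
    "default_screening_config",
]

logger = logging.getLogger(__name__)

COVARIATE_CODES: dict[str, dict[str, float]] = {
    "sex": {"male": 1.0, "female": 0.0},
    "smoking": {"ever": 1.0, "never": 0.0},
    "stage": {"I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0},
    "pathotype": {"adenocarcinoma": 0.0, "squamous": 1.0},
}

_COVARIATES = ("sex", "age", "smoking", "pathotype", "stage")


class ScreeningConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningGroup:
    """A matched-subgroup design for one target covariate."""

    target_covariate: str
    filters: Mapping[str, object] = field(default_factory=dict)
    balance: Mapping[str, int] | None = None  # per-level quota on the target
    group_size: int | None = None  # used when no balance quota applies

    def __post_init__(self) -> None:
        if self.target_covariate not in _COVARIATES:
            raise ScreeningConfigError(f"unknown covariate {self.target_covariate!r}")
        if self.balance is None and self.group_size is None:
            raise ScreeningConfigError("group needs either balance quotas or a group_size")
        if self.target_covariate in self.filters and self.balance is not None:
            raise ScreeningConfigError("filters must not constrain the quota-balanced target")

    @property
    def size(self) -> int:
        if self.balance is not None:
            return int(sum(self.balance.values()))
        assert self.group_size is not None
        return int(self.group_size)


@dataclass
class ScreeningConfig:
    confidence: float = 0.95
    rs_thresholds: dict[int, float] = field(default_factory=lambda: {60: 0.305, 52: 0.321})
    alpha_fallback: bool = False
    groups: dict[str, ScreeningGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n, thr in self.rs_thresholds.items():
            if not 0 < thr < 1:
                raise ScreeningConfigError(f"threshold for n={n} must be in (0,1), got {thr}")

    def threshold_for(self, n: int) -> float:
        if n in self.rs_thresholds:
            return self.rs_thresholds[n]
        if self.alpha_fallback:
            return critical_rho(n, 1.0 - self.confidence)
        raise ScreeningConfigError(
            f"no |rho| threshold configured for group size {n} and alpha_fallback is off"
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreeningConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        groups = {
            name: ScreeningGroup(
                target_covariate=name,
                filters=entry.get("filters", {}),
                balance=entry.get("balance"),
                group_size=entry.get("group_size"),
            )
            for name, entry in doc.get("groups", {}).items()
        }
        return cls(
            confidence=float(doc.get("confidence", 0.95)),
            rs_thresholds={int(k): float(v) for k, v in doc.get("rs_thresholds", {}).items()},
            alpha_fallback=bool(doc.get("alpha_fallback", False)),
            groups=groups,
        )


def default_screening_config() -> ScreeningConfig:
    path = Path(str(resources.files("bloodhof").joinpath("data", "screening.yaml")))
    return ScreeningConfig.from_file(path)


def clinical_frame(panels: Iterable[LabPanel]) -> pd.DataFrame:
    """Clinical covariates of a cohort, indexed by patient id."""
    rows = []
    for p in panels:
        rows.append(
            {
                "patient_id": p.patient_id,
                **{c: p.clinical.get(c) for c in _COVARIATES},
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def encode_covariate(clinical: pd.DataFrame, covariate: str) -> pd.Series:
    """Numeric encoding of a clinical covariate (documented coding)."""
    if covariate == "age":
        return clinical["age"].astype(float)
    try:
        codes = COVARIATE_CODES[covariate]
    except KeyError:
        raise ScreeningConfigError(f"unknown covariate {covariate!r}") from None
    return clinical[covariate].map(codes).astype(float)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def critical_rho(n: int, alpha: float) -> float:
    """|rho| threshold from the two-sided t-approximation.

    Inverts t = r sqrt((n-2)/(1-r^2)) at the central-t critical value
    with n-2 degrees of freedom: r = t / sqrt(t^2 + n - 2).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = stats.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    return float(t / np.sqrt(t**2 + n - 2))


def _eligible(clinical: pd.DataFrame, filters: Mapping[str, object]) -> pd.Series:
    mask = pd.Series(True, index=clinical.index)
    for key, value in filters.items():
        if key == "age":
            lo, hi = value  # type: ignore[misc]
            mask &= clinical["age"].astype(float).between(float(lo), float(hi))
        else:
            mask &= clinical[key] == value
    return mask


def build_group(
    panels: Iterable[LabPanel] | pd.DataFrame,
    group: ScreeningGroup,
    seed: int,
) -> list[str]:
    """Sample a matched subgroup; quotas are met exactly or an error names
    the failing quota.  Reproducible given the seed."""
    clinical = panels if isinstance(panels, pd.DataFrame) else clinical_frame(panels)
    rng = np.random.default_rng(seed)
    eligible = clinical[_eligible(clinical, group.filters)]
    chosen: list[str] = []
    if group.balance is not None:
        for level, quota in group.balance.items():
            pool = eligible[eligible[group.target_covariate] == level].index.to_numpy()
            if len(pool) < quota:
                raise ValueError(
                    f"quota infeasible: need {quota} patients with "
                    f"{group.target_covariate}={level!r}, only {len(pool)} eligible"
                )
            chosen.extend(rng.choice(pool, size=quota, replace=False).tolist())
    else:
        pool = eligible.index.to_numpy()
        if len(pool) < group.size:
            raise ValueError(
                f"quota infeasible: need {group.size} eligible patients, have {len(pool)}"
            )
        chosen.extend(rng.choice(pool, size=group.size, replace=False).tolist())
    return chosen


def screen_features(
    matrix: FeatureMatrix | pd.DataFrame,
    covariate: pd.Series | np.ndarray,
    config: ScreeningConfig | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Spearman-screen every feature column against an encoded covariate.

    Returns a frame (feature, n_used, rho, passed) sorted by |rho|
    descending; the threshold comes from the config by group size unless
    given explicitly.  Pairwise-complete observations only; columns that
    are all-missing or constant are excluded (logged).
    """
    values = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != len(values):
        raise ValueError("covariate length does not match the matrix")
    if threshold is None:
        config = config or default_screening_config()
        threshold = config.threshold_for(len(values))
    rows = []
    for name in values.columns:
        col = values[name].to_numpy(dtype=float)
        ok = np.isfinite(col) & np.isfinite(cov)
        if ok.sum() < 3:
            logger.info("screening: %s excluded (fewer than 3 complete pairs)", name)
            continue
        x, y = col[ok], cov[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.info("screening: %s excluded (constant vector)", name)
            continue
        rho = spearman_rho(x, y)
        rows.append(
            {"feature": name, "n_used": int(ok.sum()), "rho": rho, "passed": abs(rho) >= threshold}
        )
    out = pd.DataFrame(rows, columns=["feature", "n_used", "rho", "passed"])
    if len(out):
        out = out.reindex(out["rho"].abs().sort_values(ascending=False).index)
        out = out.reset_index(drop=True)
    out.attrs["threshold"] = threshold
    return out
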