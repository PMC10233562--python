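"""Feature evaluation on lab panels.

A :class:`LabPanel` holds one patient's pre-treatment low-order features
(LOFs: measured analytes with units) plus clinical covariates.  This
module evaluates any registry feature on a panel and builds cohort-level
feature matrices.

Missing data are never imputed.  Any cell that cannot be computed
carries a machine-readable reason (``absent-analyte``,
``zero-denominator``, ``domain-error``, ``missing-uln``) instead of a
value, mirroring a cohort design that excludes rather than imputes
incomplete blood panels.

Derivations applied when an input is absent but derivable:

* ``BMI = Weight[kg] / Height[m]^2``;
* ``IdealWeight`` from the Lorentz height/sex formula
  (men: H - 100 - (H - 150)/4; women: H - 100 - (H - 150)/2.5, H in cm),
  used by GNRI when no ideal body mass is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .expressions import ABSENT, DOMAIN, NO_ULN, OK, REASON_LABELS, ZERODIV
from .registry import (
    Condition,
    FeatureDefinition,
    FormulaVariant,
    Registry,
    ScoreRule,
)
from .units import MissingULNError, ReferenceIntervals, default_reference_intervals

__all__ = [
    "LabPanel",
    "FeatureValue",
    "FeatureMatrix",
    "FeatureEngine",
    "evaluate_variant",
    "apply_score_bands",
    "compute_feature",
    "compute_matrix",
]

_EPS = 1e-12

_SEX_CODES = {"male": 1.0, "female": 0.0}


@dataclass
class LabPanel:
    """One patient's analyte measurements (with units) and clinical data."""

    patient_id: str
    measurements: dict[str, tuple[float, str]] = field(default_factory=dict)
    clinical: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, (value, _unit) in self.measurements.items():
            if not np.isfinite(value):
                raise ValueError(f"{self.patient_id}: non-finite value for {code}")


@dataclass(frozen=True)
class FeatureValue:
    feature: str
    variant_id: int
    value: float | None
    reason: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.value is None


@dataclass
class FeatureMatrix:
    """Patients x features matrix with per-cell missingness reasons."""

    values: pd.DataFrame  # float, NaN where missing
    reasons: pd.DataFrame  # int8 reason codes (0 = ok)
    provenance: dict = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        return list(self.values.index)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def missingness_summary(self) -> pd.DataFrame:
        """Per-feature counts of each missingness reason."""
        rows = []
        for col in self.reasons.columns:
            codes = self.reasons[col].to_numpy()
            rows.append(
                {
                    "feature": col,
                    "n_missing": int((codes != OK).sum()),
                    **{
                        REASON_LABELS[c]: int((codes == c).sum())
                        for c in (ABSENT, ZERODIV, DOMAIN, NO_ULN)
                    },
                }
            )
        return pd.DataFrame(rows).set_index("feature")


def _panel_table(
    panels: Iterable[LabPanel], registry: Registry
) -> tuple[pd.DataFrame, np.ndarray]:
    """Canonical-unit analyte table plus a sex code vector (NaN unknown)."""
    panels = list(panels)
    ids = [p.patient_id for p in panels]
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    units = registry.units
    data: dict[str, np.ndarray] = {
        code: np.full(len(panels), np.nan) for code in units.analytes
    }
    sex = np.full(len(panels), np.nan)
    for i, panel in enumerate(panels):
        for code, (value, unit) in panel.measurements.items():
            data[code][i] = units.to_canonical(value, code, unit)
        if "age" in panel.clinical and np.isnan(data["Age"][i]):
            data["Age"][i] = float(panel.clinical["age"])  # type: ignore[arg-type]
        s = panel.clinical.get("sex")
        if s is not None:
            sex[i] = _SEX_CODES[str(s)]
    data["Sex"] = np.where(np.isnan(data["Sex"]), sex, data["Sex"])
    sex = data["Sex"]
    table = pd.DataFrame(data, index=ids)
    _derive_inputs(table)
    return table, sex


def _derive_inputs(table: pd.DataFrame) -> None:
    height, weight, sex = (table[c].to_numpy() for c in ("Height", "Weight", "Sex"))
    with np.errstate(all="ignore"):
        bmi = weight / height**2
        need = table["BMI"].isna().to_numpy() & np.isfinite(bmi)
        table.loc[need, "BMI"] = bmi[need]
        h_cm = height * 100.0
        lorentz = np.where(
            sex == 1.0,
            h_cm - 100.0 - (h_cm - 150.0) / 4.0,
            h_cm - 100.0 - (h_cm - 150.0) / 2.5,
        )
        ok = np.isfinite(lorentz) & np.isfinite(sex)
        need = table["IdealWeight"].isna().to_numpy() & ok
        table.loc[need, "IdealWeight"] = lorentz[need]


class FeatureEngine:
    """Vectorized evaluator for registry features over a cohort table."""

    def __init__(
        self,
        registry: Registry,
        intervals: ReferenceIntervals | None = None,
        variant_policy: Mapping[str, int] | None = None,
    ) -> None:
        self.registry = registry
        self.intervals = intervals or default_reference_intervals()
        self.variant_policy = dict(variant_policy or {})

    def _uln_map(self, analytes: Iterable[str]) -> dict[str, float | None]:
        out: dict[str, float | None] = {}
        for code in analytes:
            try:
                out[code] = self.intervals.uln(code)
            except MissingULNError:
                out[code] = None
        return out

    def _variant_for(self, feat: FeatureDefinition, pinned: int | None) -> FormulaVariant:
        if pinned is not None:
            return feat.variant(pinned)
        return feat.variant(self.variant_policy.get(feat.canonical_abbr, 1))

    def evaluate(
        self, name: str, table: pd.DataFrame, _seen: frozenset[str] = frozenset()
    ) -> tuple[np.ndarray, np.ndarray, FeatureDefinition, int]:
        """Evaluate feature ``name`` (canonical or alias) on a cohort table.

        Returns (values, reason codes, definition, variant id).  Inverse
        aliases return the reciprocal of the canonical value.  A bare
        analyte code (a LOF) passes through as its canonical-unit column.
        """
        if name not in self.registry and name in self.registry.units:
            values = table[name].to_numpy(dtype=float)
            reasons = np.where(np.isfinite(values), OK, ABSENT).astype(np.int8)
            return values, reasons, None, 0
        res = self.registry.get_definition(name)
        feat = res.definition
        variant = self._variant_for(feat, res.variant)
        if feat.canonical_abbr in _seen:
            raise RecursionError(f"cyclic feature reference through {feat.canonical_abbr}")
        seen = _seen | {feat.canonical_abbr}
        if variant.expression is not None:
            values, reasons = self._eval_expression(variant, table)
        else:
            values, reasons = self._eval_rules(variant.rules, table, seen)
        if res.inverse:
            with np.errstate(all="ignore"):
                near_zero = np.abs(values) < _EPS
                inv = np.where(near_zero, np.nan, 1.0 / np.where(near_zero, 1.0, values))
            reasons = np.where((reasons == OK) & near_zero, ZERODIV, reasons).astype(np.int8)
            values = np.where(reasons == OK, inv, np.nan)
        return values, reasons, feat, variant.variant_id

    def _eval_expression(
        self, variant: FormulaVariant, table: pd.DataFrame
    ) -> tuple[np.ndarray, np.ndarray]:
        expr = variant.expression
        assert expr is not None
        units = self.registry.units
        env: dict[str, np.ndarray] = {}
        for code in expr.analytes:
            col = table[code].to_numpy(dtype=float)
            unit = variant.unit_context.get(code)
            if unit is not None:
                col = units.from_canonical(col, code, unit)  # purely multiplicative
            env[code] = col
        uln: dict[str, float | None] = {}
        for code in expr.uln_analytes:
            limit = self._uln_map([code])[code]
            if limit is not None:
                unit = variant.unit_context.get(code)
                if unit is not None:
                    limit = units.from_canonical(limit, code, unit)
            uln[code] = limit
        return expr.evaluate(env, uln=uln, n=len(table))

    def _condition_inputs(
        self, cond: Condition, table: pd.DataFrame, seen: frozenset[str]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Values, reasons and the (possibly per-patient) cutoff for a condition."""
        units = self.registry.units
        n = len(table)
        if cond.on in units:
            values = table[cond.on].to_numpy(dtype=float)
            if cond.unit is not None:
                values = units.from_canonical(values, cond.on, cond.unit)
            reasons = np.where(np.isfinite(values), OK, ABSENT).astype(np.int8)
        else:
            values, reasons, _, _ = self.evaluate(cond.on, table, seen)
        if cond.cutoff is not None:
            cutoff = np.full(n, float(cond.cutoff))
        elif cond.uln_multiple is not None:
            limit = self._uln_map([cond.on]).get(cond.on)
            if limit is None:
                return values, np.full(n, NO_ULN, dtype=np.int8), np.full(n, np.nan)
            if cond.unit is not None:
                limit = units.from_canonical(limit, cond.on, cond.unit)
            cutoff = np.full(n, cond.uln_multiple * limit)
        else:
            assert cond.cutoff_by_sex is not None
            sex = table["Sex"].to_numpy(dtype=float)
            cutoff = np.where(
                sex == 1.0,
                cond.cutoff_by_sex["male"],
                np.where(sex == 0.0, cond.cutoff_by_sex["female"], np.nan),
            )
            reasons = np.where((reasons == OK) & ~np.isfinite(cutoff), ABSENT, reasons).astype(
                np.int8
            )
        return values, reasons, cutoff

    @staticmethod
    def _compare(values: np.ndarray, op: str, cutoff: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            if op == "<":
                return values < cutoff
            if op == "<=":
                return values <= cutoff
            if op == ">":
                return values > cutoff
            return values >= cutoff

    def _eval_rules(
        self, rules: tuple[ScoreRule, ...], table: pd.DataFrame, seen: frozenset[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        n = len(table)
        total = np.zeros(n)
        reasons = np.zeros(n, dtype=np.int8)
        for rule in rules:
            points, rule_reasons = self._eval_rule(rule, table, seen)
            total = total + points
            reasons = np.where(reasons != OK, reasons, rule_reasons).astype(np.int8)
        values = np.where(reasons == OK, total, np.nan)
        return values, reasons

    def _eval_rule(
        self, rule: ScoreRule, table: pd.DataFrame, seen: frozenset[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        n = len(table)
        if rule.kind == "threshold":
            fired = np.zeros(n, dtype=bool)
            reasons = np.zeros(n, dtype=np.int8)
            for cond in rule.conditions:
                values, r, cutoff = self._condition_inputs(cond, table, seen)
                fired |= self._compare(values, cond.op, cutoff)
                reasons = np.where(reasons != OK, reasons, r).astype(np.int8)
            return np.where(fired, float(rule.points), 0.0), reasons
        if rule.kind == "band":
            first = next(c for c, _ in rule.bands if c is not None)
            values, reasons, _ = self._condition_inputs(first, table, seen)
            points = np.full(n, np.nan)
            for cond, pts in rule.bands:
                if cond is None:
                    points = np.where(np.isnan(points), float(pts), points)
                else:
                    _, _, cutoff = self._condition_inputs(cond, table, seen)
                    hit = self._compare(values, cond.op, cutoff) & np.isnan(points)
                    points = np.where(hit, float(pts), points)
            return np.where(reasons == OK, points, 0.0), reasons
        # cases: first satisfied conjunction wins
        points = np.full(n, np.nan)
        reasons = np.zeros(n, dtype=np.int8)
        for when, pts in rule.cases:
            if when is None:
                points = np.where(np.isnan(points), float(pts), points)
                continue
            hit = np.ones(n, dtype=bool)
            for cond in when:
                values, r, cutoff = self._condition_inputs(cond, table, seen)
                hit &= self._compare(values, cond.op, cutoff)
                reasons = np.where(reasons != OK, reasons, r).astype(np.int8)
            points = np.where(np.isnan(points) & hit, float(pts), points)
        return np.where(reasons == OK, points, 0.0), reasons

    # -- cohort-level ---------------------------------------------------------

    def compute_matrix(
        self,
        panels: Iterable[LabPanel],
        features: Iterable[str] | None = None,
    ) -> FeatureMatrix:
        panels = list(panels)
        if not panels:
            raise ValueError("empty cohort")
        table, _ = _panel_table(panels, self.registry)
        names = list(features) if features is not None else self.registry.canonical_order()
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names requested")
        values: dict[str, np.ndarray] = {}
        reasons: dict[str, np.ndarray] = {}
        for name in names:
            v, r, _, _ = self.evaluate(name, table)
            values[name] = v
            reasons[name] = r
        return FeatureMatrix(
            values=pd.DataFrame(values, index=table.index),
            reasons=pd.DataFrame(reasons, index=table.index, dtype=np.int8),
            provenance={
                "registry_version": self.registry.version,
                "variant_policy": dict(self.variant_policy),
                "n_patients": len(panels),
            },
        )


# -- single-panel convenience API ---------------------------------------------


def _single(engine: FeatureEngine, name: str, panel: LabPanel) -> FeatureValue:
    table, _ = _panel_table([panel], engine.registry)
    values, reasons, feat, variant_id = engine.evaluate(name, table)
    label = feat.canonical_abbr if feat is not None else name
    if reasons[0] != OK:
        return FeatureValue(label, variant_id, None, REASON_LABELS[int(reasons[0])])
    return FeatureValue(label, variant_id, float(values[0]))


def evaluate_variant(
    variant: FormulaVariant,
    panel: LabPanel,
    registry: Registry,
    intervals: ReferenceIntervals | None = None,
    feature: str = "<anonymous>",
) -> FeatureValue:
    """Evaluate one arithmetic formula variant on a single panel."""
    engine = FeatureEngine(registry, intervals)
    table, _ = _panel_table([panel], registry)
    values, reasons = engine._eval_expression(variant, table)
    if reasons[0] != OK:
        return FeatureValue(feature, variant.variant_id, None, REASON_LABELS[int(reasons[0])])
    return FeatureValue(feature, variant.variant_id, float(values[0]))


def apply_score_bands(
    rules: tuple[ScoreRule, ...],
    panel: LabPanel,
    registry: Registry,
    intervals: ReferenceIntervals | None = None,
    feature: str = "<anonymous>",
    variant_id: int = 1,
) -> FeatureValue:
    """Apply a scoring rule set to a single panel."""
    engine = FeatureEngine(registry, intervals)
    table, _ = _panel_table([panel], registry)
    values, reasons = engine._eval_rules(rules, table, frozenset())
    if reasons[0] != OK:
        return FeatureValue(feature, variant_id, None, REASON_LABELS[int(reasons[0])])
    return FeatureValue(feature, variant_id, float(values[0]))


def compute_feature(
    registry: Registry,
    name: str,
    panel: LabPanel,
    intervals: ReferenceIntervals | None = None,
    variant_policy: Mapping[str, int] | None = None,
) -> FeatureValue:
    """Compute a feature (by canonical name or alias) on a single panel."""
    return _single(FeatureEngine(registry, intervals, variant_policy), name, panel)


def compute_matrix(
    registry: Registry,
    panels: Iterable[LabPanel],
    features: Iterable[str] | None = None,
    intervals: ReferenceIntervals | None = None,
    variant_policy: Mapping[str, int] | None = None,
) -> FeatureMatrix:
    """Compute a patients x features matrix (default: all catalog features)."""
    return FeatureEngine(registry, intervals, variant_policy).compute_matrix(panels, features)
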