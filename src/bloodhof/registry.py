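"""The high-order feature (HOF) registry.

A HOF is a derived blood-test index: a ratio/product of analytes
(proportional, e.g. NLR = Neu/Lymph), a formula with constants or
transforms (composite, e.g. dNLR, ALBI), or a sum of cutoff-assigned
points (scoring, e.g. GPS, CONUT, LIPI).  The packaged catalog holds the
110 curated features (76 proportional, 6 composite, 28 scoring) with
every reported formula/cutoff variant, reported aliases, and inverse
aliases (names that denote the reciprocal ratio, e.g. MLR vs LMR).

The registry is loaded from a YAML catalog so cutoff variants are
user-editable; this module validates it and provides name resolution.
The conflict tokens "GLR" and "LLR", each reported for unrelated
formulas, are reserved: looking them up raises :class:`AmbiguousNameError`
naming the disambiguated forms.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .expressions import Expression
from .units import UnitRegistry, default_unit_registry

__all__ = [
    "RegistryError",
    "UnknownFeatureError",
    "AmbiguousNameError",
    "Condition",
    "ScoreRule",
    "FormulaVariant",
    "Alias",
    "FeatureDefinition",
    "NameResolution",
    "Registry",
    "load_registry",
    "default_registry",
    "CATEGORIES",
]

CATEGORIES = ("proportional", "composite", "scoring")

_OPS = ("<", "<=", ">", ">=")


class RegistryError(ValueError):
    """The catalog document is malformed or inconsistent."""


class UnknownFeatureError(KeyError):
    def __init__(self, name: str, candidates: list[str]):
        self.name = name
        self.candidates = candidates
        hint = f"; did you mean {', '.join(candidates)}?" if candidates else ""
        super().__init__(f"unknown feature name {name!r}{hint}")


class AmbiguousNameError(KeyError):
    def __init__(self, name: str, resolutions: list[str]):
        self.name = name
        self.resolutions = list(resolutions)
        super().__init__(
            f"{name!r} is a reserved ambiguous abbreviation; use one of: "
            + ", ".join(resolutions)
        )


@dataclass(frozen=True)
class Condition:
    """A single comparison ``value <op> cutoff`` in a scoring rule.

    ``on`` is an analyte code or a (possibly aliased) feature name.  The
    cutoff may be fixed, sex-specific, or a multiple of the analyte's ULN.
    """

    on: str
    op: str
    cutoff: float | None = None
    cutoff_by_sex: dict[str, float] | None = None
    uln_multiple: float | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise RegistryError(f"unknown comparison operator {self.op!r}")
        n_cut = sum(x is not None for x in (self.cutoff, self.cutoff_by_sex, self.uln_multiple))
        if n_cut != 1:
            raise RegistryError(f"condition on {self.on!r} needs exactly one cutoff form")


@dataclass(frozen=True)
class ScoreRule:
    """One point-assigning rule of a scoring feature.

    Exactly one of:
      * ``conditions`` with ``points`` — threshold rule, possibly a
        disjunction (``any_of``) over the same quantity;
      * ``bands`` — ordered (Condition, points) bands over one quantity,
        first match wins, with a mandatory final else-band;
      * ``cases`` — ordered (conjunction-of-Conditions, points) cases,
        first satisfied case wins, final else-case mandatory.
    """

    kind: str  # 'threshold' | 'band' | 'cases'
    conditions: tuple[Condition, ...] = ()
    points: int = 0
    bands: tuple[tuple[Condition | None, int], ...] = ()
    cases: tuple[tuple[tuple[Condition, ...] | None, int], ...] = ()
    note: str | None = None

    def referenced(self) -> set[str]:
        refs = {c.on for c in self.conditions}
        refs |= {c.on for c, _ in self.bands if c is not None}
        for when, _ in self.cases:
            if when is not None:
                refs |= {c.on for c in when}
        return refs

    def max_points(self) -> int:
        if self.kind == "threshold":
            return self.points
        if self.kind == "band":
            return max(p for _, p in self.bands)
        return max(p for _, p in self.cases)


@dataclass(frozen=True)
class FormulaVariant:
    """One printed formula (or cutoff set) of a feature."""

    variant_id: int
    expression: Expression | None = None
    rules: tuple[ScoreRule, ...] = ()
    unit_context: dict[str, str] = field(default_factory=dict)
    source_note: str | None = None
    required_analytes: frozenset[str] = frozenset()  # filled by Registry

    @property
    def is_scoring(self) -> bool:
        return self.expression is None


@dataclass(frozen=True)
class Alias:
    name: str
    inverse: bool = False
    variant: int | None = None


@dataclass(frozen=True)
class FeatureDefinition:
    canonical_abbr: str
    full_name: str
    category: str
    variants: tuple[FormulaVariant, ...]
    aliases: tuple[Alias, ...] = ()
    score_range: tuple[int, int] | None = None

    def variant(self, variant_id: int) -> FormulaVariant:
        for v in self.variants:
            if v.variant_id == variant_id:
                return v
        raise RegistryError(f"{self.canonical_abbr}: no variant {variant_id}")


@dataclass(frozen=True)
class NameResolution:
    """Result of a name lookup: the definition, the inverse flag, and the
    variant the matched alias pins (None = caller's variant policy)."""

    definition: FeatureDefinition
    inverse: bool
    variant: int | None = None
    matched: str = ""

    def __iter__(self):
        # allow `definition, inverse = registry.get_definition(name)`
        yield self.definition
        yield self.inverse


def _normalize_keys(raw: dict) -> dict:
    # YAML 1.1 reads a bare `on:` key as boolean True; map it back
    return {("on" if k is True else k): v for k, v in raw.items()}


def _parse_condition(raw: dict, default_points: bool = False) -> tuple[Condition, int]:
    raw = _normalize_keys(raw)
    cond = Condition(
        on=str(raw["on"]),
        op=str(raw["op"]),
        cutoff=raw.get("cutoff"),
        cutoff_by_sex=raw.get("cutoff_by_sex"),
        uln_multiple=raw.get("uln_multiple"),
        unit=raw.get("unit"),
    )
    return cond, int(raw.get("points", 0))


def _parse_rule(raw: dict) -> ScoreRule:
    raw = _normalize_keys(raw)
    note = raw.get("note")
    if "bands" in raw:
        on, unit = str(raw["on"]), raw.get("unit")
        bands: list[tuple[Condition | None, int]] = []
        for b in raw["bands"]:
            if b.get("else"):
                bands.append((None, int(b["points"])))
            else:
                bands.append(
                    (Condition(on=on, op=str(b["op"]), cutoff=b["cutoff"], unit=unit), int(b["points"]))
                )
        if bands[-1][0] is not None:
            raise RegistryError(f"band rule on {on!r} must end with an else band")
        return ScoreRule(kind="band", bands=tuple(bands), note=note)
    if "cases" in raw:
        cases: list[tuple[tuple[Condition, ...] | None, int]] = []
        for c in raw["cases"]:
            if c.get("else"):
                cases.append((None, int(c["points"])))
            else:
                when = tuple(_parse_condition(w)[0] for w in c["when"])
                cases.append((when, int(c["points"])))
        if cases[-1][0] is not None:
            raise RegistryError("cases rule must end with an else case")
        return ScoreRule(kind="cases", cases=tuple(cases), note=note)
    if "any" in raw:
        on, unit = str(raw["on"]), raw.get("unit")
        conds = tuple(
            Condition(on=on, op=str(a["op"]), cutoff=a["cutoff"], unit=unit) for a in raw["any"]
        )
        return ScoreRule(kind="threshold", conditions=conds, points=int(raw["points"]), note=note)
    cond, points = _parse_condition(raw)
    return ScoreRule(kind="threshold", conditions=(cond,), points=points, note=note)


class Registry:
    """Validated catalog of features with name resolution."""

    def __init__(
        self,
        features: list[FeatureDefinition],
        version: str,
        reserved_ambiguous: dict[str, list[str]] | None = None,
        units: UnitRegistry | None = None,
    ) -> None:
        self.version = version
        self.units = units or default_unit_registry()
        self.reserved_ambiguous = dict(reserved_ambiguous or {})
        self._features: dict[str, FeatureDefinition] = {}
        self._aliases: dict[str, tuple[str, Alias]] = {}
        for feat in features:
            if feat.canonical_abbr in self._features:
                raise RegistryError(f"duplicate canonical abbreviation {feat.canonical_abbr!r}")
            self._features[feat.canonical_abbr] = feat
        for feat in features:
            for alias in feat.aliases:
                if alias.name in self.reserved_ambiguous:
                    raise RegistryError(
                        f"{feat.canonical_abbr}: {alias.name!r} is reserved ambiguous and "
                        "must not be registered as a plain alias"
                    )
                if alias.name in self._features or alias.name in self._aliases:
                    raise RegistryError(f"alias {alias.name!r} collides with an existing name")
                if alias.inverse and feat.category != "proportional":
                    raise RegistryError(
                        f"{feat.canonical_abbr}: inverse alias {alias.name!r} on a "
                        f"{feat.category} feature (only strictly positive ratios invert)"
                    )
                self._aliases[alias.name] = (feat.canonical_abbr, alias)
        self._features = {k: self._with_required(v) for k, v in self._features.items()}
        self._validate_analytes()

    # -- construction helpers -------------------------------------------------

    def _with_required(self, feat: FeatureDefinition) -> FeatureDefinition:
        variants = tuple(
            FormulaVariant(
                variant_id=v.variant_id,
                expression=v.expression,
                rules=v.rules,
                unit_context=v.unit_context,
                source_note=v.source_note,
                required_analytes=frozenset(self._required_analytes(feat, v, set())),
            )
            for v in feat.variants
        )
        return FeatureDefinition(
            canonical_abbr=feat.canonical_abbr,
            full_name=feat.full_name,
            category=feat.category,
            variants=variants,
            aliases=feat.aliases,
            score_range=feat.score_range,
        )

    def _required_analytes(
        self, feat: FeatureDefinition, variant: FormulaVariant, seen: set[str]
    ) -> set[str]:
        if feat.canonical_abbr in seen:
            raise RegistryError(f"cyclic feature reference through {feat.canonical_abbr!r}")
        seen = seen | {feat.canonical_abbr}
        if variant.expression is not None:
            return set(variant.expression.analytes)
        out: set[str] = set()
        for rule in variant.rules:
            for ref in rule.referenced():
                if ref in self.units:
                    out.add(ref)
                else:
                    sub, sub_alias = self._resolve_raw(ref)
                    sub_variant = sub.variant(sub_alias.variant if sub_alias and sub_alias.variant else 1)
                    out |= self._required_analytes(sub, sub_variant, seen)
            # sex-specific cutoffs read the patient's sex
            for cond in rule.conditions + tuple(c for c, _ in rule.bands if c) + tuple(
                c for when, _ in rule.cases if when for c in when
            ):
                if cond.cutoff_by_sex is not None:
                    out.add("Sex")
        return out

    def _resolve_raw(self, name: str) -> tuple[FeatureDefinition, Alias | None]:
        if name in self._features:
            return self._features[name], None
        if name in self._aliases:
            canon, alias = self._aliases[name]
            return self._features[canon], alias
        if name in self.reserved_ambiguous:
            raise AmbiguousNameError(name, self.reserved_ambiguous[name])
        raise UnknownFeatureError(name, self._nearest(name))

    def _validate_analytes(self) -> None:
        for feat in self._features.values():
            for v in feat.variants:
                for code in v.required_analytes:
                    if code not in self.units:
                        raise RegistryError(
                            f"feature {feat.canonical_abbr!r} references unknown analyte {code!r}"
                        )
                for code, unit in v.unit_context.items():
                    self.units.convert(1.0, code, unit, unit)  # raises if unregistered

    # -- public API -----------------------------------------------------------

    @property
    def features(self) -> dict[str, FeatureDefinition]:
        return dict(self._features)

    def __contains__(self, name: str) -> bool:
        return name in self._features or name in self._aliases

    def __len__(self) -> int:
        return len(self._features)

    def canonical_order(self) -> list[str]:
        """Canonical abbreviations in catalog (table) order."""
        return list(self._features)

    def list_features(self, category: str | None = None) -> list[str]:
        if category is not None and category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
        names = [
            f.canonical_abbr
            for f in self._features.values()
            if category is None or f.category == category
        ]
        return sorted(names)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for f in self._features.values():
            counts[f.category] += 1
        return counts

    def get_definition(self, name: str) -> NameResolution:
        feat, alias = self._resolve_raw(name)
        if alias is None:
            return NameResolution(feat, inverse=False, variant=None, matched=name)
        return NameResolution(feat, inverse=alias.inverse, variant=alias.variant, matched=name)

    def _nearest(self, name: str, n: int = 3) -> list[str]:
        pool = list(self._features) + list(self._aliases)
        return difflib.get_close_matches(name, pool, n=n, cutoff=0.5)

    def alias_names(self) -> list[str]:
        return list(self._aliases)

    def inverse_aliases(self) -> list[tuple[str, str]]:
        """(alias, canonical) pairs for every inverse-flagged alias."""
        return [
            (name, canon) for name, (canon, alias) in self._aliases.items() if alias.inverse
        ]

    def to_dict(self) -> dict:
        """Serialize back to the catalog-document structure."""
        out: dict = {"version": self.version, "reserved_ambiguous": self.reserved_ambiguous, "features": []}
        for feat in self._features.values():
            entry: dict = {
                "abbr": feat.canonical_abbr,
                "name": feat.full_name,
                "category": feat.category,
                "variants": [],
            }
            if feat.score_range is not None:
                entry["score_range"] = list(feat.score_range)
            if feat.aliases:
                entry["aliases"] = [
                    {
                        "name": a.name,
                        **({"inverse": True} if a.inverse else {}),
                        **({"variant": a.variant} if a.variant else {}),
                    }
                    for a in feat.aliases
                ]
            for v in feat.variants:
                v_entry: dict = {}
                if v.expression is not None:
                    v_entry["expr"] = v.expression.text
                    if v.unit_context:
                        v_entry["units"] = dict(v.unit_context)
                else:
                    v_entry["rules"] = [_rule_to_dict(r) for r in v.rules]
                if v.source_note:
                    v_entry["note"] = v.source_note
                entry["variants"].append(v_entry)
            out["features"].append(entry)
        return out


def _cond_to_dict(c: Condition, with_points: int | None = None) -> dict:
    d: dict = {"on": c.on, "op": c.op}
    if c.unit is not None:
        d["unit"] = c.unit
    if c.cutoff is not None:
        d["cutoff"] = c.cutoff
    if c.cutoff_by_sex is not None:
        d["cutoff_by_sex"] = dict(c.cutoff_by_sex)
    if c.uln_multiple is not None:
        d["uln_multiple"] = c.uln_multiple
    if with_points is not None:
        d["points"] = with_points
    return d


def _rule_to_dict(rule: ScoreRule) -> dict:
    d: dict
    if rule.kind == "band":
        first = next(c for c, _ in rule.bands if c is not None)
        d = {"on": first.on}
        if first.unit is not None:
            d["unit"] = first.unit
        d["bands"] = [
            {"else": True, "points": p} if c is None else {"op": c.op, "cutoff": c.cutoff, "points": p}
            for c, p in rule.bands
        ]
    elif rule.kind == "cases":
        d = {
            "cases": [
                {"else": True, "points": p}
                if when is None
                else {"when": [_cond_to_dict(c) for c in when], "points": p}
                for when, p in rule.cases
            ]
        }
    elif len(rule.conditions) > 1:
        first = rule.conditions[0]
        d = {"on": first.on}
        if first.unit is not None:
            d["unit"] = first.unit
        d["any"] = [{"op": c.op, "cutoff": c.cutoff} for c in rule.conditions]
        d["points"] = rule.points
    else:
        d = _cond_to_dict(rule.conditions[0], with_points=rule.points)
    if rule.note:
        d["note"] = rule.note
    return d


def _parse_variant(variant_id: int, raw: dict) -> FormulaVariant:
    if "expr" in raw:
        return FormulaVariant(
            variant_id=variant_id,
            expression=Expression(raw["expr"]),
            unit_context={str(k): str(v) for k, v in raw.get("units", {}).items()},
            source_note=raw.get("note"),
        )
    if "rules" in raw:
        return FormulaVariant(
            variant_id=variant_id,
            rules=tuple(_parse_rule(r) for r in raw["rules"]),
            source_note=raw.get("note"),
        )
    raise RegistryError(f"variant {variant_id} has neither 'expr' nor 'rules'")


def load_registry(source: str | Path | dict, units: UnitRegistry | None = None) -> Registry:
    """Load and validate a catalog document (path or parsed mapping)."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    features: list[FeatureDefinition] = []
    for entry in doc["features"]:
        try:
            abbr = str(entry["abbr"])
            category = str(entry["category"])
            if category not in CATEGORIES:
                raise RegistryError(f"{abbr}: unknown category {category!r}")
            variants = tuple(
                _parse_variant(i + 1, raw) for i, raw in enumerate(entry["variants"])
            )
            score_range = entry.get("score_range")
            if category == "scoring":
                if score_range is None:
                    raise RegistryError(f"{abbr}: scoring feature needs a score_range")
                score_range = (int(score_range[0]), int(score_range[1]))
                for v in variants:
                    if not v.is_scoring:
                        raise RegistryError(f"{abbr}: scoring feature with an expression variant")
            else:
                score_range = None
                for v in variants:
                    if v.is_scoring:
                        raise RegistryError(f"{abbr}: non-scoring feature with a rule variant")
            aliases = tuple(
                Alias(
                    name=str(a["name"]),
                    inverse=bool(a.get("inverse", False)),
                    variant=a.get("variant"),
                )
                for a in entry.get("aliases", [])
            )
            features.append(
                FeatureDefinition(
                    canonical_abbr=abbr,
                    full_name=str(entry.get("name", abbr)),
                    category=category,
                    variants=variants,
                    aliases=aliases,
                    score_range=score_range,
                )
            )
        except (KeyError, TypeError) as exc:
            raise RegistryError(f"malformed catalog entry {entry.get('abbr', '?')!r}: {exc}") from exc
    return Registry(
        features,
        version=str(doc.get("version", "unversioned")),
        reserved_ambiguous=doc.get("reserved_ambiguous"),
        units=units,
    )


def default_registry(units: UnitRegistry | None = None) -> Registry:
    """The packaged 110-feature catalog."""
    path = Path(str(resources.files("bloodhof").joinpath("data", "registry.yaml")))
    return load_registry(path, units=units)
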