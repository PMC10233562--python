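"""Naming rules for high-order blood features.

The catalog follows six conventions for abbreviating derived indices:

1. prefer the abbreviation form under which a feature is most reported
   (the catalog's canonical name), not its reciprocal form;
2. prefer clinically meaningful names (e.g. LIPI over LNI) — honored by
   the shipped catalog's canonical choices, not computable;
3. products are named by initial letters (LA = Lymph x Alb), ratios add
   the suffix 'R' (LAR = Lymph/Alb);
4. orient a ratio so its cohort-median value is >= 1 and never bake
   scale coefficients into the name;
5. on a single-letter clash, disambiguate with a second letter or a
   short token (GlcLR for Glc/Lymph, GranLR for Gran/Lymph);
6. keep abbreviations to 3-6 characters (the catalog itself contains
   reported 2-letter names such as LA and NP, so a short name is a
   warning, not an error).

This module canonicalizes reported names, generates rule-compliant
abbreviations, orients ratios, and validates candidate names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .registry import AmbiguousNameError, Registry

__all__ = [
    "NameProposal",
    "Violation",
    "canonicalize",
    "propose_abbreviation",
    "orient_ratio",
    "validate_abbreviation",
]

# initial letter and the short disambiguation token used on a clash;
# token choices mirror published usage (GGLR, GlcLR, GranLR, ...).
_LETTERS: dict[str, tuple[str, str]] = {
    "WBC": ("W", "W"),
    "Neu": ("N", "Neu"),
    "Lymph": ("L", "Ly"),
    "Mono": ("M", "Mo"),
    "Eosin": ("E", "Eo"),
    "Baso": ("B", "Ba"),
    "Gran": ("G", "Gran"),
    "RBC": ("R", "RBC"),
    "HGB": ("H", "Hb"),
    "MCHC": ("M", "MCHC"),
    "Plt": ("P", "Pl"),
    "MPV": ("M", "MPV"),
    "PDW": ("P", "PDW"),
    "PCT": ("P", "Pct"),
    "RDW": ("R", "RDW"),
    "Alb": ("A", "Al"),
    "Glb": ("G", "Glb"),
    "preAlb": ("P", "Pa"),
    "CRP": ("C", "CRP"),
    "SAA": ("S", "SAA"),
    "Fib": ("F", "Fib"),
    "Ddim": ("D", "Dd"),
    "AST": ("A", "AST"),
    "ALT": ("A", "ALT"),
    "ALP": ("A", "ALP"),
    "GGT": ("G", "GG"),
    "LDH": ("L", "LDH"),
    "TBil": ("T", "TBil"),
    "Crea": ("C", "Cr"),
    "UA": ("U", "UA"),
    "Glc": ("G", "Glc"),
    "TChol": ("T", "TC"),
    "TG": ("T", "TG"),
    "HDLC": ("H", "HD"),
    "INR": ("I", "INR"),
    "Age": ("A", "Age"),
}


@dataclass
class NameProposal:
    kind: str  # 'product' | 'ratio'
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    proposed: str
    rule_trace: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Violation:
    code: str  # 'reserved-ambiguous' | 'length' | 'collision' | 'missing-R-suffix'
    severity: str  # 'error' | 'warning'
    message: str


def canonicalize(registry: Registry, name: str) -> tuple[str, bool]:
    """Map a reported name to (canonical abbreviation, inverse flag).

    Raises :class:`AmbiguousNameError` for the reserved conflict tokens
    and a not-found error (with nearest candidates) otherwise.
    """
    res = registry.get_definition(name)
    return res.definition.canonical_abbr, res.inverse


def _same_meaning(registry: Registry, name: str, analytes: set[str], kind: str) -> bool:
    try:
        res = registry.get_definition(name)
    except (KeyError, AmbiguousNameError):
        return False
    variant = res.definition.variant(res.variant or 1)
    if variant.expression is None:
        return False
    is_ratio = "/" in variant.expression.text
    return set(variant.expression.analytes) == analytes and (kind == "ratio") == is_ratio


def propose_abbreviation(
    kind: str,
    numerator: Sequence[str],
    denominator: Sequence[str] = (),
    registry: Registry | None = None,
) -> NameProposal:
    """Generate a rule-compliant abbreviation for a product or ratio.

    Initial letters are concatenated (numerator then denominator); a
    ratio takes the suffix 'R'.  If the bare name collides with a
    reserved token or an existing feature of different meaning, the
    clashing analytes are expanded to their short tokens (rule 5).
    """
    if kind not in ("product", "ratio"):
        raise ValueError("kind must be 'product' or 'ratio'")
    if not numerator:
        raise ValueError("at least one numerator analyte required")
    if kind == "product" and denominator:
        raise ValueError("a product has no denominator")
    if kind == "ratio" and not denominator:
        raise ValueError("a ratio needs a denominator")
    ordered = tuple(numerator) + tuple(denominator)
    for code in ordered:
        if code not in _LETTERS:
            raise KeyError(f"no letter registered for analyte {code!r}")
    trace = ["rule3:initial-letters" if kind == "product" else "rule3:initial-letters+R-suffix"]

    def build(expanded: set[str]) -> str:
        parts = [_LETTERS[c][1] if c in expanded else _LETTERS[c][0] for c in ordered]
        return "".join(parts) + ("R" if kind == "ratio" else "")

    analytes = set(ordered)
    expanded: set[str] = set()
    proposed = build(expanded)
    if registry is not None:
        collides = proposed in registry.reserved_ambiguous or (
            proposed in registry and not _same_meaning(registry, proposed, analytes, kind)
        )
        for code in ordered:
            if not collides:
                break
            expanded.add(code)
            proposed = build(expanded)
            trace.append(f"rule5:expanded-{code}")
            collides = proposed in registry.reserved_ambiguous or (
                proposed in registry and not _same_meaning(registry, proposed, analytes, kind)
            )
    warnings = []
    if not 3 <= len(proposed) <= 6:
        warnings.append(f"rule6:length-{len(proposed)}-outside-3-6")
    return NameProposal(
        kind=kind,
        numerator=tuple(numerator),
        denominator=tuple(denominator),
        proposed=proposed,
        rule_trace=trace,
        warnings=warnings,
    )


def orient_ratio(
    numerator: Sequence[str],
    denominator: Sequence[str],
    medians: Mapping[str, float],
) -> tuple[tuple[str, ...], tuple[str, ...], bool]:
    """Orient a ratio so the cohort-median ratio is >= 1 (rule 4).

    Returns (numerator, denominator, swapped).  The median ratio is the
    ratio of the products of the analyte medians; an exact tie keeps the
    caller's order.
    """
    num_prod = den_prod = 1.0
    for code in numerator:
        m = float(medians[code])
        if m <= 0:
            raise ValueError(f"median of {code} must be positive, got {m}")
        num_prod *= m
    for code in denominator:
        m = float(medians[code])
        if m <= 0:
            raise ValueError(f"median of {code} must be positive, got {m}")
        den_prod *= m
    if num_prod / den_prod >= 1.0:
        return tuple(numerator), tuple(denominator), False
    return tuple(denominator), tuple(numerator), True


def validate_abbreviation(registry: Registry, name: str) -> list[Violation]:
    """Check a candidate abbreviation against the naming rules."""
    violations: list[Violation] = []
    if name in registry.reserved_ambiguous:
        violations.append(
            Violation(
                "reserved-ambiguous",
                "error",
                f"{name!r} is reserved (conflicting reported meanings: "
                + ", ".join(registry.reserved_ambiguous[name])
                + ")",
            )
        )
        return violations
    if len(name) > 6:
        violations.append(
            Violation("length", "error", f"{name!r} has {len(name)} characters (rule 6: 3-6)")
        )
    elif len(name) < 3:
        violations.append(
            Violation(
                "length",
                "warning",
                f"{name!r} has {len(name)} characters; rule 6 advises 3-6 "
                "(reported 2-letter names such as LA are tolerated)",
            )
        )
    if name in registry:
        res = registry.get_definition(name)
        variant = res.definition.variants[0]
        if (
            res.definition.category == "proportional"
            and variant.expression is not None
            and "/" in variant.expression.text
            and not name.endswith("R")
        ):
            violations.append(
                Violation(
                    "missing-R-suffix",
                    "warning",
                    f"{name!r} denotes a ratio but lacks the 'R' suffix (rule 3)",
                )
            )
    return violations
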