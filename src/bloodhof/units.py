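"""Analyte units: canonical units, conversions, and reference intervals.

Every analyte known to the feature registry has exactly one canonical unit
(cell counts in 10^9/L, albumin in g/L, bilirubin in umol/L, enzymes in
IU/L, ...).  Formulas and cutoffs in the feature catalog are stated in
explicit units; values are converted to those units before any arithmetic
or comparison.  All registered conversions are purely multiplicative.

Reference intervals supply the upper limit of normal (ULN) required by
ULN-relative formulas such as APRI ``(AST/AST_ULN)/Plt * 100`` and the
LIPI LDH cutoff.  The packaged defaults are generic adult intervals and
should be overridden with laboratory-specific values for real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "UnitError",
    "MissingULNError",
    "UnitRegistry",
    "ReferenceInterval",
    "ReferenceIntervals",
    "default_unit_registry",
    "default_reference_intervals",
]


class UnitError(KeyError):
    """Raised for an unknown analyte or an unregistered unit."""


class MissingULNError(LookupError):
    """Raised when a formula needs an upper limit of normal that is not configured."""


def _data_path(name: str) -> Path:
    return Path(str(resources.files("bloodhof").joinpath("data", name)))


@dataclass(frozen=True)
class ReferenceInterval:
    analyte: str
    lower: float | None
    upper: float | None

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None and not self.lower < self.upper:
            raise ValueError(f"{self.analyte}: reference interval lower must be < upper")


class UnitRegistry:
    """Registered units and conversion factors per analyte."""

    def __init__(self, spec: dict) -> None:
        self._analytes: dict[str, dict] = {}
        self._synonyms: dict[str, str] = dict(spec.get("unit_synonyms", {}))
        for code, entry in spec["analytes"].items():
            units = {str(u): float(f) for u, f in entry["units"].items()}
            canonical = str(entry["canonical"])
            if units.get(canonical) != 1.0:
                raise ValueError(f"{code}: canonical unit {canonical!r} must have factor 1")
            if any(f <= 0 for f in units.values()):
                raise ValueError(f"{code}: conversion factors must be strictly positive")
            self._analytes[code] = {
                "name": entry.get("name", code),
                "canonical": canonical,
                "units": units,
            }

    @classmethod
    def from_file(cls, path: str | Path) -> "UnitRegistry":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh))

    @property
    def analytes(self) -> list[str]:
        return list(self._analytes)

    def __contains__(self, analyte: str) -> bool:
        return analyte in self._analytes

    def display_name(self, analyte: str) -> str:
        return self._entry(analyte)["name"]

    def canonical_unit(self, analyte: str) -> str:
        return self._entry(analyte)["canonical"]

    def _entry(self, analyte: str) -> dict:
        try:
            return self._analytes[analyte]
        except KeyError:
            raise UnitError(f"unknown analyte code {analyte!r}") from None

    def _factor(self, analyte: str, unit: str) -> float:
        entry = self._entry(analyte)
        unit = self._synonyms.get(unit, unit)
        try:
            return entry["units"][unit]
        except KeyError:
            known = ", ".join(sorted(entry["units"]))
            raise UnitError(
                f"unit {unit!r} is not registered for analyte {analyte!r} (known: {known})"
            ) from None

    def convert(self, value: float, analyte: str, from_unit: str, to_unit: str) -> float:
        """Convert ``value`` of ``analyte`` between two registered units."""
        f_from = self._factor(analyte, from_unit)
        f_to = self._factor(analyte, to_unit)
        if f_from == f_to:
            return value
        return value * (f_from / f_to)

    def to_canonical(self, value: float, analyte: str, unit: str) -> float:
        return value * self._factor(analyte, unit)

    def from_canonical(self, value: float, analyte: str, unit: str) -> float:
        return value / self._factor(analyte, unit)


class ReferenceIntervals:
    """Reference intervals keyed by analyte, in canonical units."""

    def __init__(self, intervals: dict[str, ReferenceInterval]) -> None:
        self._intervals = dict(intervals)

    @classmethod
    def from_file(cls, path: str | Path) -> "ReferenceIntervals":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)["intervals"]
        return cls(
            {
                code: ReferenceInterval(code, entry.get("lower"), entry.get("upper"))
                for code, entry in raw.items()
            }
        )

    def __contains__(self, analyte: str) -> bool:
        return analyte in self._intervals

    def get(self, analyte: str) -> ReferenceInterval | None:
        return self._intervals.get(analyte)

    def uln(self, analyte: str) -> float:
        """Upper limit of normal for ``analyte`` in its canonical unit."""
        interval = self._intervals.get(analyte)
        if interval is None or interval.upper is None:
            raise MissingULNError(
                f"no upper limit of normal configured for {analyte!r}; "
                "supply one in the reference-interval file"
            )
        return interval.upper

    def replace(self, analyte: str, lower: float | None, upper: float | None) -> None:
        self._intervals[analyte] = ReferenceInterval(analyte, lower, upper)


def default_unit_registry() -> UnitRegistry:
    return UnitRegistry.from_file(_data_path("units.yaml"))


def default_reference_intervals() -> ReferenceIntervals:
    return ReferenceIntervals.from_file(_data_path("reference_intervals.yaml"))
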