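"""Delimited-text readers and writers.

Lab panels are read from CSV/TSV in either dialect:

* long format — columns ``patient_id, analyte, value, unit`` plus
  optional clinical columns (age, sex, smoking, stage, pathotype),
  repeated per row;
* wide format — one row per patient, one column per analyte; a column
  header may carry the unit as ``"Alb: g/dL"`` (otherwise the analyte's
  canonical unit is assumed).

Values are converted to canonical units on ingest.  Feature matrices are
written as wide CSV with a provenance header comment; missing cells are
empty and their reasons go to a ``<stem>.reasons.csv`` sidecar.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .compute import FeatureMatrix, LabPanel
from .expressions import OK, REASON_LABELS
from .survival import SurvivalRecord
from .units import UnitRegistry, default_unit_registry

__all__ = [
    "read_lab_table",
    "write_lab_table",
    "write_feature_table",
    "read_survival_table",
    "write_survival_table",
]

_CLINICAL_COLUMNS = ("age", "sex", "smoking", "stage", "pathotype")


class TableFormatError(ValueError):
    pass


def _detect_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_lab_table(
    path: str | Path,
    units: UnitRegistry | None = None,
    delimiter: str | None = None,
) -> list[LabPanel]:
    """Read lab panels; dialect auto-detected from the header row."""
    units = units or default_unit_registry()
    df = pd.read_csv(path, sep=_detect_delimiter(path, delimiter), comment="#", dtype=str)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "patient_id" not in cols:
        raise TableFormatError(f"{path}: no 'patient_id' column")
    if {"analyte", "value"} <= set(cols):
        return _read_long(df, units, path)
    return _read_wide(df, units, path)


def _parse_value(raw: object, path, row: int) -> float:
    try:
        return float(raw)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise TableFormatError(f"{path}: non-numeric value {raw!r} at data row {row}") from None


def _read_long(df: pd.DataFrame, units: UnitRegistry, path) -> list[LabPanel]:
    panels: dict[str, LabPanel] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        pid = str(rec["patient_id"])
        panel = panels.setdefault(pid, LabPanel(patient_id=pid))
        analyte = str(rec["analyte"]).strip()
        if analyte not in units:
            raise TableFormatError(
                f"{path}: unknown analyte {analyte!r} at data row {i}; "
                f"valid codes: {', '.join(units.analytes)}"
            )
        value = _parse_value(rec["value"], path, i)
        unit = str(rec.get("unit") or units.canonical_unit(analyte)).strip()
        canonical = units.to_canonical(value, analyte, unit)
        panel.measurements[analyte] = (canonical, units.canonical_unit(analyte))
        for col in _CLINICAL_COLUMNS:
            raw = rec.get(col)
            if raw is not None and not (isinstance(raw, float) and np.isnan(raw)):
                panel.clinical[col] = float(raw) if col == "age" else str(raw)
    return list(panels.values())


def _read_wide(df: pd.DataFrame, units: UnitRegistry, path) -> list[LabPanel]:
    # header "Alb: g/dL" carries the unit; bare "Alb" means canonical
    analyte_cols: list[tuple[str, str, str]] = []  # (column, analyte, unit)
    for col in df.columns:
        if col == "patient_id" or col in _CLINICAL_COLUMNS:
            continue
        name, _, unit = (part.strip() for part in col.partition(":"))
        if name not in units:
            raise TableFormatError(
                f"{path}: unknown analyte column {name!r}; valid codes: "
                + ", ".join(units.analytes)
            )
        analyte_cols.append((col, name, unit or units.canonical_unit(name)))
    panels = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        panel = LabPanel(patient_id=str(rec["patient_id"]))
        for col, analyte, unit in analyte_cols:
            raw = rec[col]
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
                continue
            value = _parse_value(raw, path, i)
            panel.measurements[analyte] = (
                units.to_canonical(value, analyte, unit),
                units.canonical_unit(analyte),
            )
        for col in _CLINICAL_COLUMNS:
            raw = rec.get(col)
            if raw is not None and not (isinstance(raw, float) and np.isnan(raw)):
                panel.clinical[col] = float(raw) if col == "age" else str(raw)
        panels.append(panel)
    return panels


def write_lab_table(panels: Iterable[LabPanel], path: str | Path) -> None:
    """Write panels in long format (canonical units)."""
    rows = []
    for p in panels:
        for analyte, (value, unit) in p.measurements.items():
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "analyte": analyte,
                    "value": repr(float(value)),
                    "unit": unit,
                    **{c: p.clinical.get(c, "") for c in _CLINICAL_COLUMNS},
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV with a provenance header comment.

    Missing cells are empty; a sidecar ``<stem>.reasons.csv`` lists
    (patient_id, feature, reason) for every missing cell.  Output is
    deterministic: identical inputs give byte-identical files.
    """
    if matrix.values.empty:
        raise ValueError("refusing to write an empty feature matrix")
    path = Path(path)
    prov = matrix.provenance
    header = (
        f"# bloodhof feature matrix; registry_version={prov.get('registry_version', '?')}; "
        f"variant_policy={prov.get('variant_policy', {})!r}; seed={prov.get('seed', 'none')}\n"
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        out = matrix.values.copy()
        out.insert(0, "patient_id", out.index)
        out.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")
    reasons = []
    for col in matrix.reasons.columns:
        codes = matrix.reasons[col]
        for pid in codes.index[codes != OK]:
            reasons.append(
                {"patient_id": pid, "feature": col, "reason": REASON_LABELS[int(codes[pid])]}
            )
    sidecar = path.with_suffix(".reasons.csv")
    pd.DataFrame(reasons, columns=["patient_id", "feature", "reason"]).to_csv(
        sidecar, index=False, lineterminator="\n"
    )


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, comment="#")
    required = {"patient_id", "time", "event"}
    if not required <= set(df.columns):
        raise TableFormatError(f"{path}: survival table needs columns {sorted(required)}")
    return [
        SurvivalRecord(str(r.patient_id), float(r.time), int(r.event))
        for r in df.itertuples(index=False)
    ]


def write_survival_table(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": r.patient_id, "time": r.time, "event": r.event} for r in records]
    ).to_csv(path, index=False, lineterminator="\n")
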