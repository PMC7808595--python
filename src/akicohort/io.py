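"""Delimited-text readers/writers for cohort data.

Two files make up a cohort: ``patients.csv`` (one row per patient) and
``labs.csv`` (one row per creatinine and/or dipstick measurement).  UTF-8,
comma-delimited, RFC-4180 quoting, header row mandatory.  Missing values are
empty fields — never sentinel numbers.  All creatinine on disk is μmol/l.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .types import (
    Cohort,
    CreatinineSample,
    DipstickResult,
    Disposition,
    PatientRecord,
    Phase,
    ProteinGrade,
    Sex,
    SymptomProfile,
    SYMPTOM_FIELDS,
    Visit,
)


class SchemaError(ValueError):
    """A mandatory column is missing or the file set is malformed."""


class RowError(ValueError):
    """One or more rows violate the data contract; row indices are reported."""

    def __init__(self, problems: list[tuple[str, int, str]]):
        self.problems = problems
        lines = [f"{fname} row {idx}: {msg}" for fname, idx, msg in problems]
        super().__init__("invalid rows:\n" + "\n".join(lines))


PATIENT_COLUMNS = (
    ["patient_id", "age_years", "sex", "ethnicity", "country", "phase", "is_pregnant"]
    + [f"sym_{name}" for name in SYMPTOM_FIELDS]
    + [
        "known_ckd_history",
        "disposition",
        "hours_in_facility",
        "dialysis_indicated",
        "dialyzed",
        "received_oral_fluids",
        "received_iv_fluids",
        "received_diuretics",
        "death_time_h",
        "last_contact_time_h",
    ]
)

LAB_COLUMNS = ["patient_id", "visit", "time_h", "creatinine_umol_l", "dipstick_protein"]

_MANDATORY_PATIENT = {"patient_id", "age_years", "sex", "phase"}
_FLOAT_FMT = "%.17g"  # shortest exact representation; well over 6 significant digits


def _parse_bool(v, default: bool = False) -> bool:
    if v is None or v == "":
        return default
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no", ""):
        return False
    raise ValueError(f"unparseable boolean {v!r}")


def _opt_float(v) -> Optional[float]:
    if v is None or v == "" or (isinstance(v, float) and pd.isna(v)):
        return None
    return float(v)


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing file: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def read_cohort(path: str | Path) -> Cohort:
    """Materialize a cohort from ``<path>/patients.csv`` + ``<path>/labs.csv``.

    Rows violating the data contract are collected and reported together in a
    row-addressed :class:`RowError`; a missing mandatory column raises
    :class:`SchemaError` naming the column.  Record order follows the file.
    """
    path = Path(path)
    patients = _read_csv(path / "patients.csv")
    labs = _read_csv(path / "labs.csv")

    for col in sorted(_MANDATORY_PATIENT - set(patients.columns)):
        raise SchemaError(f"patients.csv: missing mandatory column {col!r}")
    for col in [c for c in LAB_COLUMNS if c not in labs.columns]:
        raise SchemaError(f"labs.csv: missing mandatory column {col!r}")

    problems: list[tuple[str, int, str]] = []

    labs_by_patient: dict[str, list[tuple[int, dict]]] = {}
    for idx, row in enumerate(labs.to_dict("records")):
        labs_by_patient.setdefault(str(row["patient_id"]), []).append((idx, row))

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(patients.to_dict("records")):
        pid = str(row["patient_id"])
        if pid in seen:
            raise RowError([("patients.csv", idx, f"duplicate patient_id {pid!r}")])
        seen.add(pid)
        try:
            records.append(_parse_patient(row, labs_by_patient.get(pid, [])))
        except (ValueError, KeyError) as exc:
            problems.append(("patients.csv", idx, str(exc)))
    if problems:
        raise RowError(problems)
    return Cohort(records=records, provenance={"source": str(path)})


def _parse_patient(row: dict, lab_rows: list[tuple[int, dict]]) -> PatientRecord:
    symptoms = SymptomProfile(
        is_pregnant=_parse_bool(row.get("is_pregnant")),
        **{name: _parse_bool(row.get(f"sym_{name}")) for name in SYMPTOM_FIELDS},
    )
    series: list[CreatinineSample] = []
    dips: list[DipstickResult] = []
    for lab_idx, lab in lab_rows:
        visit = Visit(lab["visit"]) if lab.get("visit") else Visit.other
        time_h = _opt_float(lab.get("time_h"))
        if time_h is None:
            raise ValueError(f"labs.csv row {lab_idx}: time_h is mandatory")
        scr = _opt_float(lab.get("creatinine_umol_l"))
        if scr is not None:
            try:
                series.append(CreatinineSample(value=scr, time=time_h, visit=visit))
            except ValueError as exc:
                raise ValueError(f"labs.csv row {lab_idx}: {exc}") from None
        grade = lab.get("dipstick_protein")
        if grade not in (None, ""):
            dips.append(
                DipstickResult(
                    protein_grade=ProteinGrade.from_label(grade),
                    visit=visit,
                    time=time_h,
                )
            )
    disposition = row.get("disposition") or None
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        age_years=float(row["age_years"]),
        sex=Sex(row["sex"]),
        ethnicity=row.get("ethnicity") or None,
        country=row.get("country") or None,
        phase=Phase(row["phase"]),
        symptoms=symptoms,
        known_ckd_history=_parse_bool(row.get("known_ckd_history")),
        creatinine_series=series,
        dipsticks=dips,
        disposition=Disposition(disposition) if disposition else None,
        hours_in_facility=_opt_float(row.get("hours_in_facility")),
        dialysis_indicated=_parse_bool(row.get("dialysis_indicated")),
        dialyzed=_parse_bool(row.get("dialyzed")),
        received_oral_fluids=_parse_bool(row.get("received_oral_fluids")),
        received_iv_fluids=_parse_bool(row.get("received_iv_fluids")),
        received_diuretics=_parse_bool(row.get("received_diuretics")),
        death_time=_opt_float(row.get("death_time_h")),
        last_contact_time=_opt_float(row.get("last_contact_time_h")),
    )


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return _FLOAT_FMT % v
    return str(v)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Serialize a cohort to ``patients.csv`` + ``labs.csv`` under ``path``.

    ``read_cohort(write_cohort(c))`` reproduces every field; absent optional
    values are written as empty fields.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    patient_rows = []
    lab_rows = []
    for r in cohort:
        row = {
            "patient_id": r.patient_id,
            "age_years": _fmt(float(r.age_years)),
            "sex": r.sex.value,
            "ethnicity": r.ethnicity or "",
            "country": r.country or "",
            "phase": r.phase.value,
            "is_pregnant": _fmt(r.symptoms.is_pregnant),
        }
        for name in SYMPTOM_FIELDS:
            row[f"sym_{name}"] = _fmt(getattr(r.symptoms, name))
        row.update(
            {
                "known_ckd_history": _fmt(r.known_ckd_history),
                "disposition": r.disposition.value if r.disposition else "",
                "hours_in_facility": _fmt(r.hours_in_facility),
                "dialysis_indicated": _fmt(r.dialysis_indicated),
                "dialyzed": _fmt(r.dialyzed),
                "received_oral_fluids": _fmt(r.received_oral_fluids),
                "received_iv_fluids": _fmt(r.received_iv_fluids),
                "received_diuretics": _fmt(r.received_diuretics),
                "death_time_h": _fmt(r.death_time),
                "last_contact_time_h": _fmt(r.last_contact_time),
            }
        )
        patient_rows.append(row)
        for s in r.creatinine_series:
            lab_rows.append(
                {
                    "patient_id": r.patient_id,
                    "visit": s.visit.value,
                    "time_h": _fmt(float(s.time)),
                    "creatinine_umol_l": _fmt(float(s.value)),
                    "dipstick_protein": "",
                }
            )
        for d in r.dipsticks:
            lab_rows.append(
                {
                    "patient_id": r.patient_id,
                    "visit": d.visit.value,
                    "time_h": _fmt(float(d.time)),
                    "creatinine_umol_l": "",
                    "dipstick_protein": d.protein_grade.label,
                }
            )

    pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS).to_csv(
        path / "patients.csv", index=False
    )
    pd.DataFrame(lab_rows, columns=LAB_COLUMNS).to_csv(
        path / "labs.csv", index=False
    )
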