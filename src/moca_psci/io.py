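"""CSV interchange for cohorts, follow-up assessments and functional status.

Formats (UTF-8, header row, empty cell = missing):

* baseline cohort — one row per patient:
  ``id,age,education_years,sex,event_type,nihss,moca_raw,followed_up,follow_up_months,centre``
* follow-up tests — long format, one row per administered test:
  ``patient_id,test_name,domain,impaired``
* functional status — one row per followed-up patient:
  ``patient_id,adl_dependent,iadl_dependent,mrs,functional_loss_noncognitive``
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .adjudication import FollowUpAssessment, TestResult
from .norms import PatientRecord

__all__ = [
    "Finding",
    "ValidationReport",
    "read_baseline_csv",
    "read_followup_csvs",
    "write_baseline_csv",
    "write_followup_csvs",
    "validate_inputs",
]

BASELINE_COLUMNS = ["id", "age", "education_years", "sex", "event_type",
                    "nihss", "moca_raw", "followed_up", "follow_up_months", "centre"]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    file: str
    row: int | None  # 1-based data row; None for file-level findings
    column: str | None
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding]

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_bool(value: object) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def _opt(value: object) -> object | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        return None
    return value


def read_baseline_csv(path: str | Path) -> list[PatientRecord]:
    """Read a baseline cohort CSV; raises with row numbers on invalid rows."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in BASELINE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[PatientRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        try:
            nihss = _opt(row.get("nihss"))
            moca = _opt(row.get("moca_raw"))
            months = _opt(row.get("follow_up_months"))
            records.append(PatientRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                education_years=float(row["education_years"]),
                sex=str(row["sex"]).strip().lower(),
                event_type=str(row["event_type"]).strip(),
                nihss=None if nihss is None else int(float(nihss)),
                moca_raw=None if moca is None else int(float(moca)),
                followed_up=_parse_bool(row.get("followed_up", "false")),
                follow_up_months=None if months is None else float(months),
                centre=None if _opt(row.get("centre")) is None else str(row["centre"]),
            ))
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if problems:
        raise ValueError(f"{path}: invalid rows:\n  " + "\n  ".join(problems))
    return records


def read_followup_csvs(
    tests_path: str | Path, functional_path: str | Path
) -> list[FollowUpAssessment]:
    """Join the long-format test CSV with the per-patient functional-status CSV."""
    tests = pd.read_csv(tests_path, dtype=str, keep_default_na=False, encoding="utf-8")
    func = pd.read_csv(functional_path, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in ("patient_id", "test_name", "domain", "impaired"):
        if col not in tests.columns:
            raise ValueError(f"{tests_path}: missing column {col!r}")
    for col in ("patient_id", "adl_dependent", "iadl_dependent", "functional_loss_noncognitive"):
        if col not in func.columns:
            raise ValueError(f"{functional_path}: missing column {col!r}")

    func = func.set_index("patient_id")
    assessments = []
    for pid, grp in tests.groupby("patient_id", sort=False):
        if pid not in func.index:
            raise ValueError(f"patient {pid} has test rows but no functional-status row")
        frow = func.loc[pid]
        mrs = _opt(frow.get("mrs"))
        assessments.append(FollowUpAssessment(
            patient_id=str(pid),
            test_results=tuple(
                TestResult(test_name=str(t.test_name), domain=str(t.domain),
                           impaired=_parse_bool(t.impaired))
                for t in grp.itertuples()
            ),
            adl_dependent=_parse_bool(frow["adl_dependent"]),
            iadl_dependent=_parse_bool(frow["iadl_dependent"]),
            mrs=None if mrs is None else int(float(mrs)),
            functional_loss_noncognitive=_parse_bool(frow["functional_loss_noncognitive"]),
        ))
    return assessments


def write_baseline_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    df = pd.DataFrame([{
        "id": r.id, "age": r.age, "education_years": r.education_years,
        "sex": r.sex, "event_type": r.event_type, "nihss": r.nihss,
        "moca_raw": r.moca_raw, "followed_up": r.followed_up,
        "follow_up_months": r.follow_up_months, "centre": r.centre,
    } for r in records], columns=BASELINE_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def write_followup_csvs(
    assessments: Sequence[FollowUpAssessment],
    tests_path: str | Path,
    functional_path: str | Path,
) -> None:
    test_rows, func_rows = [], []
    for a in assessments:
        for t in a.test_results:
            test_rows.append({"patient_id": a.patient_id, "test_name": t.test_name,
                              "domain": t.domain, "impaired": t.impaired})
        func_rows.append({
            "patient_id": a.patient_id, "adl_dependent": a.adl_dependent,
            "iadl_dependent": a.iadl_dependent, "mrs": a.mrs,
            "functional_loss_noncognitive": a.functional_loss_noncognitive,
        })
    pd.DataFrame(test_rows).to_csv(tests_path, index=False, encoding="utf-8")
    pd.DataFrame(func_rows).to_csv(functional_path, index=False, encoding="utf-8")


def validate_inputs(
    baseline_path: str | Path,
    tests_path: str | Path | None = None,
    functional_path: str | Path | None = None,
) -> ValidationReport:
    """Schema/range checks with per-row diagnostics; warnings vs errors distinguished.

    Errors make the file unusable (bad types, out-of-range scores); warnings
    flag values the pipeline will handle with a documented fallback (missing
    MoCA, education 0 that will be clamped before adjustment).
    """
    findings: list[Finding] = []

    def check_baseline() -> None:
        p = Path(baseline_path)
        try:
            df = pd.read_csv(p, dtype=str, keep_default_na=False, encoding="utf-8")
        except OSError as exc:
            findings.append(Finding("error", str(p), None, None, f"unreadable: {exc}"))
            return
        for col in BASELINE_COLUMNS[:5]:
            if col not in df.columns:
                findings.append(Finding("error", str(p), None, col, "required column missing"))
        if not {"id", "age", "education_years", "moca_raw"} <= set(df.columns):
            return
        for i, row in df.iterrows():
            rowno = i + 2
            try:
                age = float(row["age"])
                if age <= 18:
                    findings.append(Finding("error", str(p), rowno, "age",
                                            f"age {age} violates the > 18 inclusion criterion"))
            except ValueError:
                findings.append(Finding("error", str(p), rowno, "age", f"not numeric: {row['age']!r}"))
            try:
                edu = float(row["education_years"])
                if edu < 0:
                    findings.append(Finding("error", str(p), rowno, "education_years", "negative"))
                elif edu < 1:
                    findings.append(Finding("warning", str(p), rowno, "education_years",
                                            "education < 1 year will be clamped before adjustment"))
            except ValueError:
                findings.append(Finding("error", str(p), rowno, "education_years",
                                        f"not numeric: {row['education_years']!r}"))
            raw = str(row["moca_raw"]).strip()
            if raw == "":
                findings.append(Finding("warning", str(p), rowno, "moca_raw",
                                        "missing baseline MoCA: excluded from score analyses"))
            else:
                try:
                    v = float(raw)
                    if not v.is_integer() or not 0 <= v <= 30:
                        findings.append(Finding("error", str(p), rowno, "moca_raw",
                                                f"must be an integer in [0, 30], got {raw}"))
                except ValueError:
                    findings.append(Finding("error", str(p), rowno, "moca_raw",
                                            f"not numeric: {raw!r}"))

    check_baseline()
    for path, required in ((tests_path, ("patient_id", "test_name", "domain", "impaired")),
                           (functional_path, ("patient_id", "adl_dependent", "iadl_dependent"))):
        if path is None:
            continue
        p = Path(path)
        try:
            df = pd.read_csv(p, dtype=str, keep_default_na=False, encoding="utf-8")
        except OSError as exc:
            findings.append(Finding("error", str(p), None, None, f"unreadable: {exc}"))
            continue
        for col in required:
            if col not in df.columns:
                findings.append(Finding("error", str(p), None, col, "required column missing"))
    return ValidationReport(findings)
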