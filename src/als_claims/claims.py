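"""Quarter-granular claims data model and CSV I/O.

The source data carry no service dates, only the calendar quarter of
service, so the calendar quarter is the atomic time unit everywhere in
this package.  Quarters are indexed as integers counted from a fixed
epoch (Q1 2005 = 0 by default, making Q4 2009 = 19); durations are
integer quarters, converted to years (x 0.25) only at reporting time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from als_claims.catalog import normalize_code

EPOCH_YEAR = 2005

SETTINGS = ("inpatient", "outpatient", "physician_office")
CODE_KINDS = ("diagnosis", "procedure_group")

#: CSV spellings of the code_kind enum.
_KIND_TO_CSV = {"diagnosis": "dx", "procedure_group": "px"}
_CSV_TO_KIND = {v: k for k, v in _KIND_TO_CSV.items()}

CLAIMS_COLUMNS = ["patient_id", "year", "quarter", "setting", "code_kind", "code"]
PATIENTS_COLUMNS = [
    "patient_id",
    "birth_year",
    "enroll_year",
    "enroll_quarter",
    "death_year",
    "death_quarter",
    "office_sample",
]


class ClaimsValidationError(ValueError):
    """Input file violates the documented dialect or an invariant."""


def quarter_of(year: int, q: int, epoch_year: int = EPOCH_YEAR) -> int:
    """Index of calendar quarter ``q`` of ``year`` relative to the epoch."""
    if not 1 <= q <= 4:
        raise ValueError(f"quarter must be in 1..4, got {q}")
    return 4 * (int(year) - epoch_year) + (int(q) - 1)


def year_quarter(index: int, epoch_year: int = EPOCH_YEAR) -> tuple[int, int]:
    """Inverse of :func:`quarter_of`: (calendar year, quarter 1..4)."""
    index = int(index)
    return epoch_year + index // 4, index % 4 + 1


@dataclass(frozen=True)
class ClaimRecord:
    """One claim line: a single code billed for a patient in a quarter."""

    patient_id: str
    quarter: int
    setting: str
    code_kind: str
    code: str

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ClaimsValidationError(f"unknown setting {self.setting!r}")
        if self.code_kind not in CODE_KINDS:
            raise ClaimsValidationError(f"unknown code_kind {self.code_kind!r}")


@dataclass
class PatientRecord:
    """A patient's enrollment metadata and their ordered claim history."""

    patient_id: str
    birth_year: int
    enrollment_start: int
    in_physician_office_sample: bool = True
    death_quarter: Optional[int] = None
    claims: list[ClaimRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.claims = sorted(self.claims, key=lambda c: c.quarter)
        self.validate()

    def validate(self) -> None:
        for claim in self.claims:
            if claim.quarter < self.enrollment_start:
                raise ClaimsValidationError(
                    f"patient {self.patient_id}: claim in quarter {claim.quarter} "
                    f"precedes enrollment start {self.enrollment_start}"
                )
        if self.death_quarter is not None and self.death_quarter < self.enrollment_start:
            raise ClaimsValidationError(
                f"patient {self.patient_id}: death quarter precedes enrollment"
            )

    def age_at(self, quarter: int) -> int:
        """Age in whole years at a quarter (calendar year difference;
        quarter granularity cannot resolve mid-year birthdays)."""
        return year_quarter(quarter)[0] - self.birth_year

    def diagnosis_claims(self) -> list[ClaimRecord]:
        return [c for c in self.claims if c.code_kind == "diagnosis"]

    def claims_in(self, first: int, last: int) -> list[ClaimRecord]:
        """Claims with quarter in the inclusive range [first, last]."""
        return [c for c in self.claims if first <= c.quarter <= last]


def _require_columns(frame: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ClaimsValidationError(f"{path}: missing column(s) {', '.join(missing)}")


def _parse_int(value, what: str, path, line: int) -> int:
    try:
        return int(str(value).strip())
    except (TypeError, ValueError):
        raise ClaimsValidationError(f"{path}, line {line}: unparseable {what} {value!r}") from None


def read_patients(path) -> list[PatientRecord]:
    """Read the patient metadata CSV (no claims attached yet)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(frame, PATIENTS_COLUMNS, path)
    patients: list[PatientRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2  # header is line 1
        pid = str(row.patient_id).strip()
        if not pid:
            raise ClaimsValidationError(f"{path}, line {line}: empty patient_id")
        if pid in seen:
            raise ClaimsValidationError(f"{path}, line {line}: duplicate patient_id {pid!r}")
        seen.add(pid)
        birth_year = _parse_int(row.birth_year, "birth_year", path, line)
        enroll = quarter_of(
            _parse_int(row.enroll_year, "enroll_year", path, line),
            _parse_int(row.enroll_quarter, "enroll_quarter", path, line),
        )
        death: Optional[int] = None
        if str(row.death_year).strip() or str(row.death_quarter).strip():
            death = quarter_of(
                _parse_int(row.death_year, "death_year", path, line),
                _parse_int(row.death_quarter, "death_quarter", path, line),
            )
        office_raw = str(row.office_sample).strip().lower()
        if office_raw not in {"0", "1", "true", "false"}:
            raise ClaimsValidationError(
                f"{path}, line {line}: office_sample must be 0/1/true/false, got {row.office_sample!r}"
            )
        patients.append(
            PatientRecord(
                patient_id=pid,
                birth_year=birth_year,
                enrollment_start=enroll,
                death_quarter=death,
                in_physician_office_sample=office_raw in {"1", "true"},
            )
        )
    return patients


def read_claims(claims_path, patients_path) -> list[PatientRecord]:
    """Read claims and patient metadata CSVs into validated patient records.

    Claim lines are grouped by patient and sorted by quarter; duplicate
    identical lines are retained (repeat claims are legitimate).  A claim
    for an unknown patient, an unparseable quarter, an unknown setting,
    or a claim preceding enrollment raises :class:`ClaimsValidationError`
    naming the offending line.
    """
    patients = read_patients(patients_path)
    by_id = {p.patient_id: p for p in patients}

    frame = pd.read_csv(claims_path, dtype=str, keep_default_na=False)
    _require_columns(frame, CLAIMS_COLUMNS, claims_path)
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        pid = str(row.patient_id).strip()
        patient = by_id.get(pid)
        if patient is None:
            raise ClaimsValidationError(
                f"{claims_path}, line {line}: claim for unknown patient {pid!r}"
            )
        quarter = quarter_of(
            _parse_int(row.year, "year", claims_path, line),
            _parse_int(row.quarter, "quarter", claims_path, line),
        )
        setting = str(row.setting).strip()
        if setting not in SETTINGS:
            raise ClaimsValidationError(
                f"{claims_path}, line {line}: unknown setting {setting!r}"
            )
        kind = _CSV_TO_KIND.get(str(row.code_kind).strip())
        if kind is None:
            raise ClaimsValidationError(
                f"{claims_path}, line {line}: code_kind must be dx or px, got {row.code_kind!r}"
            )
        code = str(row.code).strip()
        if not code:
            raise ClaimsValidationError(f"{claims_path}, line {line}: empty code")
        if kind == "diagnosis":
            code = normalize_code(code)
        if quarter < patient.enrollment_start:
            raise ClaimsValidationError(
                f"{claims_path}, line {line}: claim in quarter {quarter} precedes "
                f"enrollment start of patient {pid}"
            )
        patient.claims.append(
            ClaimRecord(patient_id=pid, quarter=quarter, setting=setting, code_kind=kind, code=code)
        )
    for patient in patients:
        patient.claims.sort(key=lambda c: c.quarter)
        patient.validate()
    return patients


def write_claims(patients: Iterable[PatientRecord], claims_path, patients_path) -> None:
    """Write patients back out in the documented CSV dialects."""
    patients = list(patients)
    with open(patients_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(PATIENTS_COLUMNS)
        for p in patients:
            ey, eq = year_quarter(p.enrollment_start)
            if p.death_quarter is not None:
                dy, dq = year_quarter(p.death_quarter)
                death_year, death_quarter = str(dy), str(dq)
            else:
                death_year = death_quarter = ""
            writer.writerow(
                [
                    p.patient_id,
                    p.birth_year,
                    ey,
                    eq,
                    death_year,
                    death_quarter,
                    1 if p.in_physician_office_sample else 0,
                ]
            )
    with open(claims_path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(CLAIMS_COLUMNS)
        for p in patients:
            for c in p.claims:
                year, quarter = year_quarter(c.quarter)
                writer.writerow(
                    [c.patient_id, year, quarter, c.setting, _KIND_TO_CSV[c.code_kind], c.code]
                )


def patients_by_id(patients: Iterable[PatientRecord]) -> dict[str, PatientRecord]:
    return {p.patient_id: p for p in patients}
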