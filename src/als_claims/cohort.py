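"""Cohort construction: inclusion/exclusion criteria and attrition.

Three cohorts are built from the claims population:

* the **ALS cohort** — patients whose first index-diagnosis claim
  (ICD-9-CM 335.20) falls in the diagnosis window, with at least two
  index claims, aged >= 65 at the index quarter, enrolled at least two
  years (8 quarters) before it, and present in the physician-office
  sample;
* the **time-to-diagnosis subcohort** — ALS-cohort patients whose index
  quarter falls in a later window that guarantees at least three years
  of prior claims to search for symptoms;
* the **comparison cohort** — patients with no motor neuron disease
  claims at all (the whole 335.* family), supplying reference code
  frequencies.

The index quarter of the first ALS claim is the *diagnosis quarter*; it
anchors every lookback window downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

from als_claims.catalog import CodePattern, normalize_code
from als_claims.claims import PatientRecord, quarter_of


@dataclass(frozen=True)
class CohortCriteria:
    """Inclusion/exclusion thresholds, defaulting to the study design.

    ``diagnosis_window`` and ``ttd_window`` are inclusive quarter-index
    ranges under the Q1 2005 epoch: Q1 2007-Q4 2009 and Q1 2008-Q4 2009
    respectively.  ``min_prior_enrollment`` implements "enrolled two
    years or more before the first ALS claim" as >= 8 whole quarters.
    ``count_claims_in_window_only`` restricts the >= ``min_als_claims``
    count to the diagnosis window (the printed rule); set it False to
    count index claims anywhere in the data.
    """

    als_code: str = "335.20"
    diagnosis_window: tuple[int, int] = (quarter_of(2007, 1), quarter_of(2009, 4))
    min_als_claims: int = 2
    min_age: int = 65
    min_prior_enrollment: int = 8
    ttd_window: tuple[int, int] = (quarter_of(2008, 1), quarter_of(2009, 4))
    require_office_sample: bool = True
    mnd_exclusion_patterns: tuple[CodePattern, ...] = (CodePattern("335.X"),)
    count_claims_in_window_only: bool = True

    def __post_init__(self) -> None:
        if self.min_als_claims < 1:
            raise ValueError("min_als_claims must be >= 1")
        for lo, hi in (self.diagnosis_window, self.ttd_window):
            if lo > hi:
                raise ValueError("windows must be non-empty")
        if not (
            self.diagnosis_window[0] <= self.ttd_window[0]
            and self.ttd_window[1] <= self.diagnosis_window[1]
        ):
            raise ValueError("ttd_window must lie within diagnosis_window")
        patterns = tuple(
            p if isinstance(p, CodePattern) else CodePattern(p)
            for p in self.mnd_exclusion_patterns
        )
        object.__setattr__(self, "mnd_exclusion_patterns", patterns)


@dataclass
class CohortResult:
    """Cohort membership plus the attrition funnel.

    ``als_patients`` maps patient_id -> diagnosis quarter (quarter of the
    first index claim).  ``attrition`` lists (criterion label, patients
    remaining) in the order the criteria were applied.
    """

    als_patients: dict[str, int] = field(default_factory=dict)
    ttd_patients: dict[str, int] = field(default_factory=dict)
    comparison_patients: set[str] = field(default_factory=set)
    attrition: list[tuple[str, int]] = field(default_factory=list)


def _als_claim_quarters(patient: PatientRecord, als_code: str) -> list[int]:
    code = normalize_code(als_code)
    return [c.quarter for c in patient.claims if c.code_kind == "diagnosis" and c.code == code]


def index_quarter(patient: PatientRecord, criteria: CohortCriteria) -> Optional[int]:
    """Quarter of the patient's first ALS claim, or None if they have none."""
    quarters = _als_claim_quarters(patient, criteria.als_code)
    return min(quarters) if quarters else None


def criterion_predicates(
    criteria: CohortCriteria,
) -> list[tuple[str, Callable[[PatientRecord, Optional[int]], bool]]]:
    """The ordered ALS-cohort criteria as (label, predicate) pairs.

    Each predicate takes (patient, diagnosis_quarter) where the quarter
    may be None when the patient has no index claim.  Exposed so the
    criteria can be re-applied independently or in a different order;
    the final membership is order-independent (a pure conjunction).
    """
    lo, hi = criteria.diagnosis_window

    def first_claim_in_window(patient, dq):
        return dq is not None and lo <= dq <= hi

    def enough_als_claims(patient, dq):
        quarters = _als_claim_quarters(patient, criteria.als_code)
        if criteria.count_claims_in_window_only:
            quarters = [q for q in quarters if lo <= q <= hi]
        return len(quarters) >= criteria.min_als_claims

    def old_enough(patient, dq):
        return dq is not None and patient.age_at(dq) >= criteria.min_age

    def enrolled_long_enough(patient, dq):
        return dq is not None and dq - patient.enrollment_start >= criteria.min_prior_enrollment

    def in_office_sample(patient, dq):
        return patient.in_physician_office_sample or not criteria.require_office_sample

    return [
        ("first ALS claim in diagnosis window", first_claim_in_window),
        (f">= {criteria.min_als_claims} ALS claims", enough_als_claims),
        (f"age >= {criteria.min_age} at diagnosis", old_enough),
        (
            f">= {criteria.min_prior_enrollment} quarters enrolled before diagnosis",
            enrolled_long_enough,
        ),
        ("in physician office sample", in_office_sample),
    ]


def build_als_cohort(
    patients: Sequence[PatientRecord], criteria: CohortCriteria = CohortCriteria()
) -> CohortResult:
    """Apply the inclusion criteria in order and record the attrition funnel."""
    result = CohortResult()
    survivors = [(p, index_quarter(p, criteria)) for p in patients]
    result.attrition.append(("all patients", len(survivors)))
    for label, predicate in criterion_predicates(criteria):
        survivors = [(p, dq) for p, dq in survivors if predicate(p, dq)]
        result.attrition.append((label, len(survivors)))
    result.als_patients = {p.patient_id: dq for p, dq in survivors}
    return result


def build_ttd_cohort(result: CohortResult, criteria: CohortCriteria = CohortCriteria()) -> CohortResult:
    """Restrict to index quarters inside the time-to-diagnosis window.

    The later window guarantees the minimum span of prior claims needed
    to search for first symptoms, given the dataset start.
    """
    lo, hi = criteria.ttd_window
    result.ttd_patients = {pid: dq for pid, dq in result.als_patients.items() if lo <= dq <= hi}
    result.attrition.append(("first ALS claim in time-to-diagnosis window", len(result.ttd_patients)))
    return result


def build_comparison_cohort(
    patients: Sequence[PatientRecord], criteria: CohortCriteria = CohortCriteria()
) -> set[str]:
    """Patients with zero claims matching any motor-neuron-disease pattern."""
    excluded_patterns = criteria.mnd_exclusion_patterns

    def has_mnd_claim(patient: PatientRecord) -> bool:
        return any(
            c.code_kind == "diagnosis" and any(p.matches(c.code) for p in excluded_patterns)
            for c in patient.claims
        )

    return {p.patient_id for p in patients if not has_mnd_claim(p)}
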