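"""First-symptom detection, onset-type calls, and time to diagnosis.

The first-symptom rule: scanning a patient's quarters in ascending order
from enrollment through the diagnosis quarter inclusive, a quarter marks
symptom onset if it contains at least one high-likelihood symptom code,
or codes for at least two *distinct* moderate-likelihood diagnoses of
interest (two claims of the same moderate code do not suffice).  The
earliest such quarter is the onset quarter.  The onset category is read
from the union of all symptom definitions matched in that quarter: all
limb -> limb, all bulbar -> bulbar, a mix -> both.

Time to diagnosis is the quarter difference between onset and the index
diagnosis quarter, reported in years (x 0.25); onset in the diagnosis
quarter itself is a valid zero-lag call.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from als_claims.catalog import CodeCatalog, SymptomDefinition
from als_claims.claims import PatientRecord
from als_claims.prevalence import median_quarters

ONSET_CALL_CATEGORIES = ("limb", "bulbar", "both", "none")


@dataclass
class OnsetCall:
    """Per-patient result of the first-symptom rule."""

    patient_id: str
    onset_quarter: Optional[int] = None
    onset_category: str = "none"
    trigger: list[tuple[str, SymptomDefinition]] = field(default_factory=list)
    ttd_quarters: Optional[int] = None

    @property
    def ttd_years(self) -> Optional[float]:
        return None if self.ttd_quarters is None else 0.25 * self.ttd_quarters


def _quarter_matches(
    patient: PatientRecord, catalog: CodeCatalog, first: int, last: int
) -> dict[int, list[tuple[str, SymptomDefinition]]]:
    """Map quarter -> deduplicated (code, definition) pairs matched in it."""
    matched: dict[int, list[tuple[str, SymptomDefinition]]] = defaultdict(list)
    seen: set[tuple[int, str, str]] = set()
    for claim in patient.claims:
        if claim.code_kind != "diagnosis" or not first <= claim.quarter <= last:
            continue
        for definition in catalog.classify_code(claim.code):
            key = (claim.quarter, claim.code, definition.label)
            if key not in seen:
                seen.add(key)
                matched[claim.quarter].append((claim.code, definition))
    return matched


def _triggers(pairs: list[tuple[str, SymptomDefinition]]) -> bool:
    if any(d.likelihood == "high" for _, d in pairs):
        return True
    moderate_labels = {d.label for _, d in pairs if d.likelihood == "moderate"}
    return len(moderate_labels) >= 2


def classify_onset(call: OnsetCall) -> str:
    """Onset category from the triggering set: limb, bulbar, or both."""
    if not call.trigger:
        raise ValueError(f"patient {call.patient_id}: onset call has an empty trigger")
    categories = {d.category for _, d in call.trigger}
    if categories == {"limb"}:
        return "limb"
    if categories == {"bulbar"}:
        return "bulbar"
    return "both"


def find_first_symptom(
    patient: PatientRecord, catalog: CodeCatalog, diagnosis_quarter: int
) -> OnsetCall:
    """Apply the first-symptom rule up to the diagnosis quarter inclusive."""
    if diagnosis_quarter < patient.enrollment_start:
        raise ValueError(
            f"patient {patient.patient_id}: diagnosis quarter precedes enrollment"
        )
    call = OnsetCall(patient_id=patient.patient_id)
    matched = _quarter_matches(patient, catalog, patient.enrollment_start, diagnosis_quarter)
    for quarter in sorted(matched):
        pairs = matched[quarter]
        if _triggers(pairs):
            call.onset_quarter = quarter
            call.trigger = pairs
            call.onset_category = classify_onset(call)
            call.ttd_quarters = diagnosis_quarter - quarter
            break
    return call


def time_to_diagnosis(onset_quarter: int, diagnosis_quarter: int) -> float:
    """Years from symptom onset to diagnosis: 0.25 x the quarter lag."""
    if diagnosis_quarter < onset_quarter:
        raise ValueError(
            f"onset quarter {onset_quarter} is after diagnosis quarter {diagnosis_quarter}"
        )
    return 0.25 * (diagnosis_quarter - onset_quarter)


@dataclass
class OnsetSummary:
    """Cohort-level onset-type mix and median diagnostic delay."""

    n_total: int
    n_classified: int
    #: whole-percent onset-type proportions over classified patients
    proportions_pct: dict[str, int]
    #: whole-percent proportions over all patients (unclassified included)
    proportions_all_pct: dict[str, int]
    median_ttd_years: Optional[float]
    median_ttd_years_by_category: dict[str, Optional[float]]


def onset_summary(calls: Sequence[OnsetCall]) -> OnsetSummary:
    """Summarize onset calls: category mix and median time to diagnosis.

    Proportions are reported both over classified patients and over the
    whole cohort (with the unclassified remainder implicit); medians use
    midpoint interpolation for even counts.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("onset_summary requires at least one call")
    classified = [c for c in calls if c.onset_category != "none"]
    by_category: dict[str, list[OnsetCall]] = {"limb": [], "bulbar": [], "both": []}
    for call in classified:
        by_category[call.onset_category].append(call)

    def pct(count: int, denom: int) -> int:
        return int(round(100.0 * count / denom)) if denom else 0

    ttd_all = [c.ttd_years for c in classified if c.ttd_years is not None]
    medians = {
        cat: (median_quarters([c.ttd_years for c in group]) if group else None)
        for cat, group in by_category.items()
    }
    return OnsetSummary(
        n_total=len(calls),
        n_classified=len(classified),
        proportions_pct={
            cat: pct(len(group), len(classified)) for cat, group in by_category.items()
        },
        proportions_all_pct={
            cat: pct(len(group), len(calls)) for cat, group in by_category.items()
        },
        median_ttd_years=median_quarters(ttd_all) if ttd_all else None,
        median_ttd_years_by_category=medians,
    )
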