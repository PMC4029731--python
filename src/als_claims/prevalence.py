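"""Pre-diagnosis prevalence, prevalence rate ratios, and the reporting filter.

For each symptom/diagnosis group, prevalence is the percentage of ALS
cohort patients with at least one matching claim in the lookback window
— the 8 quarters immediately preceding, and excluding, the diagnosis
quarter.  The comparison prevalence is the percentage of comparison
cohort patients with a matching claim inside a fixed calendar window
(Q1 2008–Q4 2009 by default, the same 8-quarter span).  Their quotient
is the prevalence rate ratio.

Ratios are computed on unrounded percentages and rounded (half-up, one
decimal) only for display: the published ratios are reproducible from
the printed percentages only for rows where the authors' unrounded
inputs happen to round consistently, which is why rounding is deferred.
No hypothesis testing is attached to the ratios by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from als_claims.catalog import CodeGroupDefinition
from als_claims.claims import PatientRecord, quarter_of


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (the convention of the published tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def median_quarters(values: Sequence[float]) -> float:
    """Median of quarter-multiple durations, midpoint for even counts.

    The midpoint of two quarter multiples may fall between quarters
    (e.g. [2.75, 3.0] -> 2.875, displayed 2.88), which is why published
    medians are not always multiples of 0.25.
    """
    data = sorted(values)
    if not data:
        raise ValueError("median of an empty list")
    n = len(data)
    mid = n // 2
    if n % 2:
        return float(data[mid])
    return 0.5 * (data[mid - 1] + data[mid])


@dataclass(frozen=True)
class RatioResult:
    """A prevalence rate ratio with its degenerate-input flag."""

    value: float
    flag: Optional[str] = None  # None, "infinite", or "zero_over_zero"

    @property
    def display(self) -> float:
        return self.value if math.isinf(self.value) else round_half_up(self.value, 1)


@dataclass
class PrevalenceRow:
    """One row of the prevalence table (unrounded percentages)."""

    symptom_group: str
    label: str
    pre_als_pct: float
    medicare_pct: float
    ratio: RatioResult
    #: median years from first-symptom onset to diagnosis among ALS
    #: patients with the group in-window; None when not computed.
    median_ttd_years: Optional[float] = None

    @property
    def prevalence_ratio(self) -> float:
        return self.ratio.value


def _has_group_claim(patient: PatientRecord, group: CodeGroupDefinition, first: int, last: int) -> bool:
    return any(
        first <= c.quarter <= last and group.matches(c.code, c.code_kind)
        for c in patient.claims
    )


def pre_diagnosis_prevalence(
    als_patients: Mapping[str, int],
    patients: Mapping[str, PatientRecord],
    group: CodeGroupDefinition,
    lookback: int = 8,
) -> float:
    """Percent of ALS-cohort patients with a matching claim in the
    ``lookback`` quarters before (and excluding) their diagnosis quarter."""
    if lookback < 1:
        raise ValueError("lookback must be >= 1 quarter")
    if not als_patients:
        raise ValueError("empty ALS cohort")
    hits = sum(
        _has_group_claim(patients[pid], group, dq - lookback, dq - 1)
        for pid, dq in als_patients.items()
    )
    return 100.0 * hits / len(als_patients)


def comparison_prevalence(
    comparison_patients: Iterable[str],
    patients: Mapping[str, PatientRecord],
    group: CodeGroupDefinition,
    window: tuple[int, int] = (quarter_of(2008, 1), quarter_of(2009, 4)),
) -> float:
    """Percent of comparison patients with a matching claim inside the
    fixed calendar window (no per-patient anchoring)."""
    first, last = window
    if first > last:
        raise ValueError("comparison window must be non-empty")
    ids = list(comparison_patients)
    if not ids:
        raise ValueError("empty comparison cohort")
    hits = sum(_has_group_claim(patients[pid], group, first, last) for pid in ids)
    return 100.0 * hits / len(ids)


def prevalence_ratio(pre_als_pct: float, medicare_pct: float) -> RatioResult:
    """ALS-cohort prevalence divided by comparison-cohort prevalence.

    A positive numerator over a zero denominator yields an ``infinite``
    flagged sentinel; 0/0 yields 0 with a ``zero_over_zero`` flag.
    """
    if pre_als_pct < 0 or medicare_pct < 0:
        raise ValueError("prevalences must be nonnegative")
    if medicare_pct == 0:
        if pre_als_pct == 0:
            return RatioResult(0.0, flag="zero_over_zero")
        return RatioResult(math.inf, flag="infinite")
    return RatioResult(pre_als_pct / medicare_pct)


def filter_reported_rows(
    rows: Sequence[PrevalenceRow],
    min_prevalence: float = 10.0,
    min_ratio: float = 5.0,
) -> list[PrevalenceRow]:
    """Keep rows with ALS-cohort prevalence >= ``min_prevalence`` percent
    OR a prevalence ratio >= ``min_ratio``, stably sorted by descending
    ratio (the published table ordering)."""
    kept = [
        row
        for row in rows
        if row.pre_als_pct >= min_prevalence or row.ratio.value >= min_ratio
    ]
    return sorted(kept, key=lambda row: -row.ratio.value)


def build_prevalence_table(
    als_patients: Mapping[str, int],
    comparison_patients: Iterable[str],
    patients: Mapping[str, PatientRecord],
    groups: Sequence[CodeGroupDefinition],
    onset_calls: Optional[Mapping[str, "object"]] = None,
    lookback: int = 8,
    comparison_window: tuple[int, int] = (quarter_of(2008, 1), quarter_of(2009, 4)),
) -> list[PrevalenceRow]:
    """Assemble unfiltered prevalence rows for the given symptom groups.

    When ``onset_calls`` (patient_id -> onset call) is supplied, each row
    also carries the median onset-to-diagnosis delay among ALS patients
    with the group in-window whose first symptom was detected.
    """
    comparison_ids = list(comparison_patients)
    rows: list[PrevalenceRow] = []
    for group in groups:
        if group.group_kind != "symptom_or_diagnosis":
            raise ValueError(f"group {group.label!r} is not a symptom/diagnosis group")
        pre = pre_diagnosis_prevalence(als_patients, patients, group, lookback=lookback)
        med = comparison_prevalence(comparison_ids, patients, group, window=comparison_window)
        median_ttd: Optional[float] = None
        if onset_calls is not None:
            ttds = [
                onset_calls[pid].ttd_years
                for pid, dq in als_patients.items()
                if pid in onset_calls
                and onset_calls[pid].ttd_years is not None
                and _has_group_claim(patients[pid], group, dq - lookback, dq - 1)
            ]
            if ttds:
                median_ttd = median_quarters(ttds)
        rows.append(
            PrevalenceRow(
                symptom_group=group.symptom_group,
                label=group.label,
                pre_als_pct=pre,
                medicare_pct=med,
                ratio=prevalence_ratio(pre, med),
                median_ttd_years=median_ttd,
            )
        )
    return rows
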