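"""Symptom-lag distributions and diagnostic-test utilization.

The lag of a symptom is the number of quarters between a patient's first
claim carrying one of the symptom's codes (at or before the diagnosis
quarter) and the diagnosis quarter.  Lags are binned into 0-3, 4-7,
8-11, and 12+ quarters.  A symptom's lag is anchored on its own first
occurrence, independent of the onset rule: a lone moderate code cannot
trigger onset but still defines that symptom's lag.

Test utilization is the percentage of (sub)cohort patients with at least
one matching procedure claim in the 8 quarters before (and excluding)
diagnosis; the median time to diagnosis among tested patients is anchored
on the onset call.  Medians over subgroups smaller than a configurable
minimum are suppressed as "not determined" (ND), mirroring small-cell
suppression in published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from als_claims.catalog import CodeCatalog, CodeGroupDefinition
from als_claims.claims import PatientRecord
from als_claims.onset import OnsetCall
from als_claims.prevalence import median_quarters

LAG_BINS = ((0, 3), (4, 7), (8, 11), (12, None))
LAG_BIN_LABELS = ("0-3", "4-7", "8-11", "12+")

#: Below this many contributing patients a subgroup median is suppressed.
DEFAULT_ND_THRESHOLD = 11


@dataclass
class LagDistributionRow:
    """Lag summary for one symptom over the patients who carry it."""

    label: str
    n: int
    mean_quarters: float
    median_quarters: float
    bin_pcts: tuple[float, float, float, float]


@dataclass
class TestUtilizationRow:
    """Utilization of one diagnostic test in a cohort or onset subgroup."""

    label: str
    subgroup: Optional[str]  # None = whole cohort, else onset category
    n: int
    n_with_test: int
    pct_with_test: float
    median_ttd_years: Optional[float]
    not_determined: bool


def _resolve_symptom_patterns(catalog: CodeCatalog, label: str):
    """Label -> matcher, preferring analysis groups over onset definitions."""
    for group in catalog.symptom_groups():
        if group.label == label:
            return lambda code: group.matches(code, "diagnosis")
    try:
        definition = catalog.get_definition(label)
    except KeyError:
        raise KeyError(f"label {label!r} is neither an analysis group nor a symptom definition")
    return definition.matches


def bin_lag(lag: int) -> int:
    """Index of the lag bin (0-3, 4-7, 8-11, 12+) containing ``lag``."""
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    for i, (lo, hi) in enumerate(LAG_BINS):
        if lag >= lo and (hi is None or lag <= hi):
            return i
    raise AssertionError("unreachable: bins partition the nonnegative integers")


def symptom_lag_distribution(
    als_patients: Mapping[str, int],
    patients: Mapping[str, PatientRecord],
    catalog: CodeCatalog,
    symptom_labels: Sequence[str],
) -> list[LagDistributionRow]:
    """Lag mean/median/bin percentages for each listed symptom.

    Patients with no matching code at or before diagnosis are omitted
    from that symptom's row.
    """
    rows: list[LagDistributionRow] = []
    for label in symptom_labels:
        matcher = _resolve_symptom_patterns(catalog, label)
        lags: list[int] = []
        for pid, dq in als_patients.items():
            quarters = [
                c.quarter
                for c in patients[pid].claims
                if c.code_kind == "diagnosis" and c.quarter <= dq and matcher(c.code)
            ]
            if quarters:
                lags.append(dq - min(quarters))
        if not lags:
            rows.append(LagDistributionRow(label, 0, float("nan"), float("nan"), (0.0,) * 4))
            continue
        counts = [0, 0, 0, 0]
        for lag in lags:
            counts[bin_lag(lag)] += 1
        n = len(lags)
        rows.append(
            LagDistributionRow(
                label=label,
                n=n,
                mean_quarters=sum(lags) / n,
                median_quarters=median_quarters([float(v) for v in lags]),
                bin_pcts=tuple(100.0 * c / n for c in counts),
            )
        )
    return rows


def test_utilization(
    als_patients: Mapping[str, int],
    patients: Mapping[str, PatientRecord],
    test_group: CodeGroupDefinition,
    onset_calls: Optional[Mapping[str, OnsetCall]] = None,
    lookback: int = 8,
    subgroup: Optional[str] = None,
    nd_threshold: int = DEFAULT_ND_THRESHOLD,
) -> TestUtilizationRow:
    """Utilization of one diagnostic-test group, optionally restricted to
    an onset subgroup ("limb", "bulbar", or "both").

    Each patient counts at most once regardless of repeat claims.  The
    median time to diagnosis is computed over tested patients with a
    detected onset, and reported as not determined (``None``) when fewer
    than ``nd_threshold`` patients contribute.
    """
    if test_group.group_kind != "diagnostic_test":
        raise ValueError(f"group {test_group.label!r} is not a diagnostic-test group")
    members = dict(als_patients)
    if subgroup is not None:
        if onset_calls is None:
            raise ValueError("subgroup restriction requires onset calls")
        members = {
            pid: dq
            for pid, dq in members.items()
            if pid in onset_calls and onset_calls[pid].onset_category == subgroup
        }
    tested = {
        pid
        for pid, dq in members.items()
        if any(
            dq - lookback <= c.quarter <= dq - 1 and test_group.matches(c.code, c.code_kind)
            for c in patients[pid].claims
        )
    }
    pct = 100.0 * len(tested) / len(members) if members else 0.0
    median_ttd: Optional[float] = None
    not_determined = False
    if onset_calls is not None:
        ttds = [
            onset_calls[pid].ttd_years
            for pid in tested
            if pid in onset_calls and onset_calls[pid].ttd_years is not None
        ]
        if len(ttds) >= nd_threshold:
            median_ttd = median_quarters(ttds)
        else:
            not_determined = True
    return TestUtilizationRow(
        label=test_group.label,
        subgroup=subgroup,
        n=len(members),
        n_with_test=len(tested),
        pct_with_test=pct,
        median_ttd_years=median_ttd,
        not_determined=not_determined,
    )
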