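"""Shared fixtures: patient factories, random claim histories, and the
independent brute-force onset oracle used to cross-check the rule engine."""

from __future__ import annotations

import random

import pytest

from als_claims.catalog import default_catalog
from als_claims.claims import ClaimRecord, PatientRecord

#: Diagnosis codes used to build random histories: high-likelihood onset
#: codes, moderate codes, and codes the rule table does not know.
HISTORY_CODE_POOL = [
    "728.87",  # high limb
    "781.2",  # high limb
    "784.51",  # high bulbar (784.5X family)
    "787.2",  # high bulbar
    "359.1",  # high limb (359.X family)
    "719.4",  # moderate limb
    "729.5",  # moderate limb
    "728.3",  # moderate limb (728.X family)
    "999.9",  # unknown to the catalog
    "428.0",  # unknown to the catalog
    "724.2",  # analysis group only (lumbago), not an onset code
    "335.20",  # the index code itself; not a symptom
]


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def build_patient(
    pid="p1",
    birth_year=1935,
    enroll=0,
    office=True,
    dx=(),
    px=(),
    death=None,
):
    """Construct a patient from (quarter, code) claim shorthand."""
    claims = [
        ClaimRecord(pid, q, "physician_office", "diagnosis", code) for q, code in dx
    ] + [ClaimRecord(pid, q, "outpatient", "procedure_group", code) for q, code in px]
    return PatientRecord(
        patient_id=pid,
        birth_year=birth_year,
        enrollment_start=enroll,
        in_physician_office_sample=office,
        death_quarter=death,
        claims=claims,
    )


@pytest.fixture
def make_patient():
    return build_patient


def random_history(rng: random.Random, pid="r1", n_quarters=13):
    """A random claims history ending at a diagnosis quarter."""
    dq = n_quarters - 1
    dx = [(dq, "335.20"), (dq, "335.20")]
    for quarter in range(n_quarters):
        for _ in range(rng.randint(0, 3)):
            dx.append((quarter, rng.choice(HISTORY_CODE_POOL)))
    return build_patient(pid=pid, dx=dx), dq


def oracle_onset(patient, catalog, diagnosis_quarter):
    """Naive per-quarter re-classification of the first-symptom rule.

    Independently re-scans every quarter's code set, re-classifying each
    code from scratch, and returns (onset_quarter, category) or
    (None, "none").
    """
    for quarter in range(patient.enrollment_start, diagnosis_quarter + 1):
        codes = {
            c.code
            for c in patient.claims
            if c.code_kind == "diagnosis" and c.quarter == quarter
        }
        matched = {}
        for code in codes:
            for definition in catalog.symptom_definitions:
                if any(p.matches(code) for p in definition.patterns):
                    matched[definition.label] = definition
        has_high = any(d.likelihood == "high" for d in matched.values())
        n_moderate = len({d.label for d in matched.values() if d.likelihood == "moderate"})
        if has_high or n_moderate >= 2:
            categories = {d.category for d in matched.values()}
            if categories == {"limb"}:
                return quarter, "limb"
            if categories == {"bulbar"}:
                return quarter, "bulbar"
            return quarter, "both"
    return None, "none"
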