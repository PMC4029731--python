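"""Cohort criteria, attrition funnel, and comparison-cohort exclusion."""

from __future__ import annotations

import random

import pytest

from als_claims.cohort import (
    CohortCriteria,
    build_als_cohort,
    build_comparison_cohort,
    build_ttd_cohort,
    criterion_predicates,
    index_quarter,
)
from als_claims.claims import quarter_of
from conftest import build_patient


def qualifying_patient(pid, dq=14, enroll=0, birth_year=1930, office=True, extra_dx=()):
    dx = [(dq, "335.20"), (min(dq + 1, 19), "335.20"), *extra_dx]
    return build_patient(pid, birth_year=birth_year, enroll=enroll, office=office, dx=dx)


class TestAlsCohort:
    def test_single_index_claim_excluded_at_min_claims_step(self):
        patient = build_patient("p1", dx=[(14, "335.20")])
        result = build_als_cohort([patient])
        assert result.als_patients == {}
        counts = dict(result.attrition)
        assert counts["first ALS claim in diagnosis window"] == 1
        assert counts[">= 2 ALS claims"] == 0

    def test_first_claim_before_window_excluded(self):
        # first index claim Q3 2006 precedes the Q1 2007 window start
        patient = build_patient(
            "p1", dx=[(quarter_of(2006, 3), "335.20"), (14, "335.20"), (15, "335.20")]
        )
        result = build_als_cohort([patient])
        assert result.als_patients == {}

    def test_diagnosis_quarter_is_first_index_claim(self):
        patient = qualifying_patient("p1", dq=13)
        result = build_als_cohort([patient])
        assert result.als_patients == {"p1": 13}

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"birth_year": 1944},  # 64 at a 2008 diagnosis
            {"enroll": 8, "dq": 14},  # only 6 quarters of prior enrollment
            {"office": False},
        ],
    )
    def test_each_criterion_excludes(self, kwargs):
        patient = qualifying_patient("p1", **kwargs)
        assert build_als_cohort([patient]).als_patients == {}

    def test_synthetic_population_against_per_patient_oracle(self):
        """Every included patient satisfies every criterion and vice versa,
        re-checked predicate by predicate."""
        rng = random.Random(7)
        patients = []
        for i in range(60):
            patients.append(
                qualifying_patient(
                    f"q{i}",
                    dq=rng.randint(10, 19),
                    enroll=rng.choice([0, 4, 10]),
                    birth_year=rng.choice([1930, 1943, 1944]),
                    office=rng.random() < 0.8,
                )
            )
        criteria = CohortCriteria()
        result = build_als_cohort(patients, criteria)
        predicates = criterion_predicates(criteria)
        for patient in patients:
            dq = index_quarter(patient, criteria)
            should_be_in = all(pred(patient, dq) for _, pred in predicates)
            assert (patient.patient_id in result.als_patients) == should_be_in

    def test_attrition_monotone_non_increasing(self):
        rng = random.Random(3)
        patients = [
            qualifying_patient(
                f"m{i}", dq=rng.randint(9, 19), enroll=rng.choice([0, 9]), office=rng.random() < 0.5
            )
            for i in range(40)
        ]
        counts = [count for _, count in build_als_cohort(patients).attrition]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] == len(patients)

    def test_final_membership_is_order_independent(self):
        rng = random.Random(11)
        patients = [
            qualifying_patient(
                f"o{i}", dq=rng.randint(9, 19), enroll=rng.choice([0, 9]),
                birth_year=rng.choice([1930, 1944]), office=rng.random() < 0.7,
            )
            for i in range(50)
        ]
        criteria = CohortCriteria()
        reference = set(build_als_cohort(patients, criteria).als_patients)
        predicates = criterion_predicates(criteria)
        for _ in range(5):
            rng.shuffle(predicates)
            survivors = {
                p.patient_id
                for p in patients
                if all(pred(p, index_quarter(p, criteria)) for _, pred in predicates)
            }
            assert survivors == reference


class TestTtdCohort:
    def test_window_boundaries(self):
        inside = qualifying_patient("in", dq=quarter_of(2008, 2))
        outside = qualifying_patient("out", dq=quarter_of(2007, 4), extra_dx=[(13, "335.20")])
        result = build_ttd_cohort(build_als_cohort([inside, outside]))
        assert "out" in result.als_patients
        assert set(result.ttd_patients) == {"in"}

    def test_planted_mixture_counts(self):
        patients = [qualifying_patient(f"i{k}", dq=12 + k % 8) for k in range(30)]
        patients += [
            qualifying_patient(f"x{k}", dq=8 + k % 4, extra_dx=[(15, "335.20")])
            for k in range(20)
        ]
        result = build_ttd_cohort(build_als_cohort(patients))
        assert len(result.als_patients) == 50
        assert len(result.ttd_patients) == 30
        assert set(result.ttd_patients) <= set(result.als_patients)


class TestComparisonCohort:
    def test_any_mnd_family_claim_excludes(self):
        with_index = build_patient("a", dx=[(5, "335.20")])
        with_other_mnd = build_patient("b", dx=[(5, "335.21")])
        clean = build_patient("c", dx=[(5, "724.2")])
        assert build_comparison_cohort([with_index, with_other_mnd, clean]) == {"c"}

    def test_planted_background_count_and_disjointness(self):
        als = [qualifying_patient(f"a{i}") for i in range(10)]
        background = [build_patient(f"b{i}", dx=[(3, "724.2")]) for i in range(100)]
        comparison = build_comparison_cohort(als + background)
        assert len(comparison) == 100
        result = build_als_cohort(als + background)
        assert comparison.isdisjoint(result.als_patients)


class TestCriteriaValidation:
    def test_ttd_window_must_nest_in_diagnosis_window(self):
        with pytest.raises(ValueError):
            CohortCriteria(diagnosis_window=(8, 19), ttd_window=(4, 19))

    def test_count_all_claims_switch(self):
        # first index claim at the window edge, second after the window
        patient = build_patient("p1", dx=[(19, "335.20"), (21, "335.20")])
        assert build_als_cohort([patient]).als_patients == {}  # only 1 in-window claim
        relaxed = CohortCriteria(count_claims_in_window_only=False)
        assert build_als_cohort([patient], relaxed).als_patients == {"p1": 19}
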