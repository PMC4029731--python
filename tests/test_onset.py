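"""The first-symptom rule, onset-type calls, and time to diagnosis."""

from __future__ import annotations

import random

import pytest

from als_claims.onset import (
    OnsetCall,
    classify_onset,
    find_first_symptom,
    onset_summary,
    time_to_diagnosis,
)
from conftest import build_patient, oracle_onset, random_history


class TestFirstSymptomRule:
    def test_single_high_code_triggers(self, catalog):
        patient = build_patient("p", dx=[(6, "728.87"), (10, "335.20"), (10, "335.20")])
        call = find_first_symptom(patient, catalog, 10)
        assert call.onset_quarter == 6
        assert call.onset_category == "limb"
        assert {label for _, label in [(c, d.label) for c, d in call.trigger]} >= {
            "Muscle weakness (generalized)"
        }
        assert call.ttd_quarters == 4

    def test_two_distinct_moderates_required_in_one_quarter(self, catalog):
        patient = build_patient("p", dx=[(4, "719.4"), (5, "719.4"), (5, "729.5")])
        call = find_first_symptom(patient, catalog, 8)
        assert call.onset_quarter == 5  # the lone Q4 moderate does not trigger
        assert call.onset_category == "limb"

    def test_repeated_single_moderate_code_never_triggers(self, catalog):
        patient = build_patient("p", dx=[(4, "719.4"), (4, "719.4"), (4, "719.4")])
        call = find_first_symptom(patient, catalog, 8)
        assert call.onset_category == "none"
        assert call.onset_quarter is None and call.ttd_quarters is None

    def test_same_family_moderates_do_not_pair(self, catalog):
        # 728.3 and 728.71 both fall only under the moderate 728.X family:
        # one diagnosis of interest, not two
        patient = build_patient("p", dx=[(4, "728.3"), (4, "728.71")])
        assert find_first_symptom(patient, catalog, 8).onset_category == "none"

    def test_onset_in_diagnosis_quarter_is_valid(self, catalog):
        patient = build_patient("p", dx=[(9, "787.2")])
        call = find_first_symptom(patient, catalog, 9)
        assert call.onset_quarter == 9 and call.ttd_quarters == 0

    def test_diagnosis_before_enrollment_rejected(self, catalog):
        patient = build_patient("p", enroll=5)
        with pytest.raises(ValueError):
            find_first_symptom(patient, catalog, 4)

    def test_matches_bruteforce_oracle_on_random_histories(self, catalog):
        rng = random.Random(12345)
        for i in range(300):
            patient, dq = random_history(rng, pid=f"r{i}")
            call = find_first_symptom(patient, catalog, dq)
            expected_quarter, expected_category = oracle_onset(patient, catalog, dq)
            assert call.onset_quarter == expected_quarter
            assert call.onset_category == expected_category
            if expected_quarter is not None:
                assert call.ttd_quarters == dq - expected_quarter

    def test_claims_after_onset_never_change_the_call(self, catalog):
        rng = random.Random(99)
        for i in range(50):
            patient, dq = random_history(rng, pid=f"s{i}")
            call = find_first_symptom(patient, catalog, dq)
            if call.onset_quarter is None or call.onset_quarter >= dq:
                continue
            extended = build_patient(
                pid=patient.patient_id,
                dx=[(c.quarter, c.code) for c in patient.claims]
                + [(call.onset_quarter + 1, "728.87"), (dq, "787.2")],
            )
            after = find_first_symptom(extended, catalog, dq)
            assert (after.onset_quarter, after.onset_category) == (
                call.onset_quarter,
                call.onset_category,
            )

    def test_removing_a_nontriggering_claim_never_changes_the_call(self, catalog):
        patient = build_patient("p", dx=[(2, "999.9"), (3, "719.4"), (6, "728.87")])
        call = find_first_symptom(patient, catalog, 10)
        pruned = build_patient("p", dx=[(3, "719.4"), (6, "728.87")])
        slim = find_first_symptom(pruned, catalog, 10)
        assert (call.onset_quarter, call.onset_category) == (slim.onset_quarter, slim.onset_category)
        assert call.onset_quarter == 6


class TestClassifyOnset:
    def test_pure_bulbar(self, catalog):
        patient = build_patient("p", dx=[(5, "787.2")])
        assert find_first_symptom(patient, catalog, 9).onset_category == "bulbar"

    def test_concurrent_limb_and_bulbar_is_both(self, catalog):
        patient = build_patient("p", dx=[(5, "728.87"), (5, "784.3")])
        assert find_first_symptom(patient, catalog, 9).onset_category == "both"

    def test_two_moderate_limb_is_limb(self, catalog):
        patient = build_patient("p", dx=[(5, "719.4"), (5, "729.5")])
        assert find_first_symptom(patient, catalog, 9).onset_category == "limb"

    def test_empty_trigger_rejected(self):
        with pytest.raises(ValueError):
            classify_onset(OnsetCall(patient_id="p"))


class TestTimeToDiagnosis:
    @pytest.mark.parametrize("onset, dq, expected", [(10, 20, 2.5), (7, 7, 0.0), (0, 5, 1.25)])
    def test_quarter_difference_times_quarter_length(self, onset, dq, expected):
        assert time_to_diagnosis(onset, dq) == expected

    def test_onset_after_diagnosis_rejected(self):
        with pytest.raises(ValueError):
            time_to_diagnosis(9, 8)


class TestOnsetSummary:
    @staticmethod
    def _call(pid, category, ttd_quarters):
        call = OnsetCall(patient_id=pid, onset_category=category)
        if category != "none":
            call.onset_quarter = 0
            call.ttd_quarters = ttd_quarters
        return call

    def test_published_style_mix_with_one_unclassified(self):
        calls = (
            [self._call(f"l{i}", "limb", 10) for i in range(74)]
            + [self._call(f"b{i}", "bulbar", 5) for i in range(17)]
            + [self._call(f"x{i}", "both", 1) for i in range(8)]
            + [self._call("n0", "none", None)]
        )
        summary = onset_summary(calls)
        assert summary.n_total == 100 and summary.n_classified == 99
        # over all patients the mix reads 74/17/8; over classified, limb rounds up
        assert summary.proportions_all_pct == {"limb": 74, "bulbar": 17, "both": 8}
        assert summary.proportions_pct == {"limb": 75, "bulbar": 17, "both": 8}
        assert summary.median_ttd_years_by_category["limb"] == 2.5
        assert summary.median_ttd_years_by_category["bulbar"] == 1.25

    def test_median_uses_midpoint_for_even_counts(self):
        calls = [self._call("a", "limb", 4), self._call("b", "limb", 6)]
        assert onset_summary(calls).median_ttd_years == 1.25

    def test_constant_ttd_median(self):
        calls = [self._call(f"c{i}", "bulbar", 4) for i in range(5)]
        assert onset_summary(calls).median_ttd_years == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            onset_summary([])
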