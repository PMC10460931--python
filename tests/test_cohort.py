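"""Eligibility rules, predictor encoding thresholds, summaries, CSV dialect."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from pmvalidate import (
    CohortParseError,
    EmptyCohortError,
    PatientRecord,
    apply_general_exclusions,
    cohort_summary,
    encode_lowlaavar,
    encode_risc,
    lowlaavar_eligible,
    read_cohort_csv,
    risc_eligible,
    write_cohort_csv,
)


def rec(**kw):
    base = dict(
        patient_id="p1", hospital_id="h1", age_months=12, sex="male",
        outcome="survived",
    )
    base.update(kw)
    return PatientRecord(**base)


class TestExclusions:
    def test_burn_removed_clean_retained(self):
        records = [rec(exclusion_flags=frozenset({"burn"})), rec()]
        kept = apply_general_exclusions(records)
        assert kept == [records[1]]

    def test_toy_counts_and_order(self):
        records = [
            rec(patient_id="a"),
            rec(patient_id="b", exclusion_flags=frozenset({"poisoning"})),
            rec(patient_id="c"),
            rec(patient_id="d", exclusion_flags=frozenset({"strike_period"})),
            rec(patient_id="e"),
        ]
        kept = apply_general_exclusions(records)
        assert [r.patient_id for r in kept] == ["a", "c", "e"]

    def test_model_specific_flags_not_general(self):
        # cancer etc. only exclude from the infection-model cohort
        assert apply_general_exclusions([rec(exclusion_flags=frozenset({"cancer"}))])


class TestEligibility:
    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(age_months=12, cough_or_difficulty_breathing="yes",
                  danger_signs=frozenset({"grunting"})), True),
            (dict(age_months=1, cough_or_difficulty_breathing="yes",
                  danger_signs=frozenset({"grunting"})), False),
            (dict(age_months=60, cough_or_difficulty_breathing="yes",
                  danger_signs=frozenset({"grunting"})), False),
            (dict(age_months=12, cough_or_difficulty_breathing="yes", avpu="P"), True),
            (dict(age_months=12, cough_or_difficulty_breathing="yes",
                  danger_signs=frozenset({"convulsion"})), True),
            (dict(age_months=12, cough_or_difficulty_breathing="no",
                  danger_signs=frozenset({"grunting"})), False),
            (dict(age_months=12, cough_or_difficulty_breathing="yes"), False),
        ],
    )
    def test_pneumonia_danger_sign_mode(self, kw, expected):
        assert risc_eligible(rec(**kw)) is expected

    def test_pneumonia_clinical_dx_mode(self):
        r = rec(age_months=12, clinical_pneumonia_dx="yes")
        assert risc_eligible(r, mode="clinical_dx")
        assert not risc_eligible(r)  # no cough/danger signs
        assert not risc_eligible(rec(age_months=1, clinical_pneumonia_dx="yes"),
                                 mode="clinical_dx")

    @pytest.mark.parametrize(
        "kw, expected",
        [
            (dict(age_months=24, infection_suspected="yes"), True),
            (dict(age_months=24, infection_suspected="yes",
                  exclusion_flags=frozenset({"malnutrition_dx"})), False),
            (dict(age_months=5, infection_suspected="yes"), False),
            (dict(age_months=60, infection_suspected="yes"), True),
            (dict(age_months=61, infection_suspected="yes"), False),
            (dict(age_months=24, infection_suspected="no"), False),
        ],
    )
    def test_infection_model_eligibility(self, kw, expected):
        assert lowlaavar_eligible(rec(**kw)) is expected


class TestEncodeRisc:
    @pytest.mark.parametrize(
        "spo2, moderate, severe",
        [(91.0, 1, 0), (90.0, 1, 0), (92.0, 1, 0), (89.9, 0, 1), (93.0, 0, 0)],
    )
    def test_hypoxemia_thresholds(self, spo2, moderate, severe):
        e = encode_risc(rec(spo2_pct=spo2))
        assert e.values["moderate_hypoxemia"] == moderate
        assert e.values["severe_hypoxemia"] == severe

    @pytest.mark.parametrize(
        "muac, moderate, severe",
        [(110.0, 0, 1), (115.0, 1, 0), (125.0, 1, 0), (135.0, 1, 0), (136.0, 0, 0)],
    )
    def test_malnutrition_thresholds(self, muac, moderate, severe):
        e = encode_risc(rec(muac_mm=muac))
        assert e.values["moderately_malnourished"] == moderate
        assert e.values["severely_malnourished"] == severe

    @pytest.mark.parametrize("avpu, unconscious", [("A", 0), ("V", 0), ("P", 1), ("U", 1)])
    def test_avpu(self, avpu, unconscious):
        assert encode_risc(rec(avpu=avpu)).values["unconscious"] == unconscious

    def test_missing_sources_propagate(self):
        e = encode_risc(rec())
        assert {"moderate_hypoxemia", "severe_hypoxemia"} <= e.missing
        assert {"moderately_malnourished", "severely_malnourished"} <= e.missing
        assert {"unconscious", "wheeze"} <= e.missing
        assert e.values["female"] == 0.0

    @settings(max_examples=200, deadline=None)
    @given(spo2=st.floats(0, 100), muac=st.floats(50, 250))
    def test_categories_mutually_exclusive(self, spo2, muac):
        e = encode_risc(rec(spo2_pct=spo2, muac_mm=muac))
        assert e.values["moderate_hypoxemia"] + e.values["severe_hypoxemia"] <= 1
        assert (
            e.values["moderately_malnourished"] + e.values["severely_malnourished"] <= 1
        )


class TestEncodeLowlaavar:
    @pytest.mark.parametrize("bcs, abnormal", [(0, 1), (4, 1), (5, 0)])
    def test_bcs_threshold(self, bcs, abnormal):
        assert encode_lowlaavar(rec(bcs=bcs)).values["abnormal_bcs"] == abnormal

    @pytest.mark.parametrize("avpu, abnormal", [("V", 1), ("A", 0), ("P", 0)])
    def test_avpu_proxy_mode(self, avpu, abnormal):
        e = encode_lowlaavar(rec(avpu=avpu), bcs_source="avpu_proxy")
        assert e.values["abnormal_bcs"] == abnormal

    def test_passthrough_and_missing(self):
        e = encode_lowlaavar(rec(bcs=5, hiv_positive="yes", waz=-1.3, muac_mm=128.0))
        assert e.values == {
            "abnormal_bcs": 0.0, "hiv_positive": 1.0, "waz": -1.3, "muac_mm": 128.0,
        }
        e2 = encode_lowlaavar(rec())
        assert e2.missing == {"abnormal_bcs", "hiv_positive", "waz", "muac_mm"}


class TestCohortSummary:
    def test_toy_counts(self):
        records = [rec(patient_id=str(i)) for i in range(3)] + [
            rec(patient_id="d", outcome="died")
        ]
        s = cohort_summary(records, encoder="risc")
        assert (s.n_total, s.n_died) == (4, 1)
        assert s.strata == {}  # no indicator present in this toy cohort

    def test_stratum_accounting(self):
        records = [
            rec(patient_id="1", spo2_pct=85.0, outcome="died"),
            rec(patient_id="2", spo2_pct=85.0),
            rec(patient_id="3", spo2_pct=97.0),
        ]
        s = cohort_summary(records, encoder="risc")
        n, d, cfr = s.strata["severe_hypoxemia"]
        assert (n, d, cfr) == (2, 1, 50.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(EmptyCohortError):
            cohort_summary([], encoder="risc")


class TestCsvDialect:
    def test_round_trip(self, tmp_path):
        records = [
            rec(patient_id="a", spo2_pct=91.5, danger_signs=frozenset({"grunting", "stridor"})),
            rec(patient_id="b", avpu="P", bcs=3, hiv_positive="no",
                exclusion_flags=frozenset({"burn"})),
        ]
        path = tmp_path / "cohort.csv"
        write_cohort_csv(records, path)
        assert read_cohort_csv(path) == records

    def test_range_violation_reports_row(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv([rec(patient_id="ok"),
                          dataclasses.replace(rec(patient_id="bad"), spo2_pct=150.0)], path)
        with pytest.raises(CohortParseError) as exc:
            read_cohort_csv(path)
        assert exc.value.row == 3 and "spo2" in str(exc.value)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv([rec()], path)
        text = path.read_text().replace("hospital_id,", "")
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(
            line.replace("h1,", "", 1) if i else line
            for i, line in enumerate(text.splitlines())
        ))
        with pytest.raises(CohortParseError) as exc:
            read_cohort_csv(bad)
        assert "hospital_id" in str(exc.value)
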