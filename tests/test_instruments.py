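"""Questionnaire scoring, eligibility and descriptive-table behaviour."""

import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bedmot.instruments import (
    BedqResponse,
    CompletionCategory,
    MdiBand,
    MdiResponse,
    PatientRecord,
    SeverityBand,
    ValidationError,
    check_eligibility,
    classify_bedq_severity,
    completion_category,
    completion_percentages,
    completion_table,
    descriptives,
    read_cohort,
    score_bedq,
    score_mdi,
    write_cohort,
)


def make_record(**overrides) -> PatientRecord:
    base = dict(
        id="P1", age=40.0, sex="female", bmi=35.0, age_group="adult",
        motivation_aims="introjection", motivation_online="identification",
        therapy_aims_text="tekst", why_online_text="tekst",
        sessions_completed=10, followup_done=True,
        bedq_pre=15, bedq_post=10, edeq_pre=3.5, edeq_post=2.5,
        mdi_pre=23, mdi_post=18, vas_pre=50, vas_post=60,
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestBedq:
    @pytest.mark.parametrize("items,item8,item9,expected", [
        ((0,) * 7, 0, False, 0),
        ((5,) * 7, 5, True, 35),
        ((3, 2, 1, 0, 4, 5, 0), 5, True, 15),  # items 8/9 never enter the sum
    ])
    def test_sum_score(self, items, item8, item9, expected):
        assert score_bedq(BedqResponse(items, item8, item9)) == expected

    def test_permutation_invariance(self):
        items = (3, 2, 1, 0, 4, 5, 0)
        assert score_bedq(BedqResponse(items)) == score_bedq(BedqResponse(items[::-1]))

    def test_out_of_range_item_names_the_item(self):
        with pytest.raises(ValidationError, match="item 3"):
            BedqResponse((0, 0, 6, 0, 0, 0, 0))

    def test_wrong_item_count(self):
        with pytest.raises(ValidationError, match="7"):
            BedqResponse((1, 2, 3))

    @pytest.mark.parametrize("score,band", [
        (0, SeverityBand.NONE),
        (1, SeverityBand.SUBCLINICAL), (9, SeverityBand.SUBCLINICAL),
        (10, SeverityBand.MILD), (14, SeverityBand.MILD),
        (15, SeverityBand.MODERATE), (21, SeverityBand.MODERATE),
        (22, SeverityBand.SEVERE), (28, SeverityBand.SEVERE),
        (29, SeverityBand.EXTREMELY_SEVERE), (35, SeverityBand.EXTREMELY_SEVERE),
    ])
    def test_severity_bands(self, score, band):
        assert classify_bedq_severity(score) == band

    def test_bands_partition_and_monotone(self):
        bands = [classify_bedq_severity(s) for s in range(36)]
        assert all(b2 >= b1 for b1, b2 in zip(bands, bands[1:]))
        assert set(bands) == set(SeverityBand)

    def test_score_out_of_range(self):
        with pytest.raises(ValidationError):
            classify_bedq_severity(36)


class TestMdi:
    @pytest.mark.parametrize("items,total,band", [
        ((0,) * 10, 0, MdiBand.NONE),
        ((3,) * 7 + (0,) * 3, 21, MdiBand.MILD),
        ((4,) * 7 + (1, 1, 1), 31, MdiBand.SEVERE),
    ])
    def test_total_and_band(self, items, total, band):
        assert score_mdi(MdiResponse(items)) == (total, band)

    def test_wrong_item_count(self):
        with pytest.raises(ValidationError, match="10"):
            MdiResponse((1, 2, 3))


class TestEligibility:
    def test_eligible_below_both_rules(self):
        assert check_eligibility(15, 23).eligible

    def test_severe_bedq_excludes_at_band_edge(self):
        result = check_eligibility(22, 0)
        assert not result.eligible
        assert any("severe BED" in r for r in result.reasons)

    def test_high_mdi_excludes(self):
        result = check_eligibility(10, 41)
        assert not result.eligible
        assert any("MDI" in r for r in result.reasons)

    def test_both_rules_both_reasons(self):
        assert len(check_eligibility(30, 45).reasons) == 2


class TestCompletion:
    @pytest.mark.parametrize("sessions,followup,expected", [
        (5, True, CompletionCategory.LOW),
        (0, False, CompletionCategory.LOW),
        (6, False, CompletionCategory.HIGH),
        (9, True, CompletionCategory.HIGH),
        (10, True, CompletionCategory.FULL),
        (10, False, CompletionCategory.HIGH),  # Full requires the follow-up
    ])
    def test_categories(self, sessions, followup, expected):
        assert completion_category(sessions, followup) == expected

    def test_full_without_followup_configurable(self):
        assert completion_category(10, False, full_requires_followup=False) \
            == CompletionCategory.FULL

    @given(st.integers(0, 9), st.integers(1, 10), st.booleans())
    def test_monotone_in_sessions(self, a, delta, followup):
        b = min(a + delta, 10)
        assert completion_category(b, followup) >= completion_category(a, followup)

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            completion_category(11, True)


class TestTables:
    def test_young_adult_percentages_match_printed_frequencies(self):
        # Full 8, High 14, Low 16 of 38 young adults
        assert completion_percentages([8, 14, 16]) == [21.05, 36.84, 42.11]

    @pytest.mark.parametrize("freqs,expected", [
        ([5], [100.0]),
        ([1, 1, 2], [25.0, 25.0, 50.0]),
    ])
    def test_percentage_arithmetic(self, freqs, expected):
        assert completion_percentages(freqs) == expected

    def test_completion_table_shape_and_sums(self):
        records = (
            [make_record(id=f"L{i}", sessions_completed=3) for i in range(2)]
            + [make_record(id=f"H{i}", sessions_completed=8) for i in range(1)]
            + [make_record(id=f"F{i}", sessions_completed=10) for i in range(1)]
            + [make_record(id="Y1", age=20, age_group="young_adult", sessions_completed=10)]
        )
        table = completion_table(records)
        for _, grp in table.groupby("age_group"):
            assert abs(grp["pct_of_age_group"].sum() - 100.0) <= 0.01
        adult = table[table.age_group == "adult"]
        assert list(adult["completion"]) == ["Full", "High", "Low"]
        assert list(adult["frequency"]) == [1, 1, 2]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            completion_table([])

    @pytest.mark.parametrize("n,n_male,expected", [
        (148, 17, 11.5),
        (3, 0, 0.0),
        (3, 1, 33.3),
    ])
    def test_percent_male(self, n, n_male, expected):
        records = [
            make_record(id=f"P{i}", sex="male" if i < n_male else "female")
            for i in range(n)
        ]
        assert descriptives(records)["pct_male"] == expected

    def test_descriptives_ranges(self):
        records = [make_record(id="A", age=20, age_group="young_adult"),
                   make_record(id="B", age=68)]
        d = descriptives(records)
        assert d["age_range"] == (20, 68)
        assert d["n_young_adults"] == 1


class TestCohortIO:
    def test_round_trip(self, tmp_path):
        records = [make_record(id="P1"), make_record(id="P2", bedq_post=None,
                                                     edeq_post=None, mdi_post=None,
                                                     vas_post=None)]
        path = tmp_path / "cohort.csv"
        write_cohort(records, path)
        back = read_cohort(path)
        assert back == records

    def test_header_mismatch_rejected(self):
        bad = io.StringIO("id,age\nP1,30\n")
        with pytest.raises(ValidationError, match="header"):
            read_cohort(bad)

    def test_validation_happens_on_read(self, tmp_path):
        records = [make_record(id="P1")]
        path = tmp_path / "cohort.csv"
        write_cohort(records, path)
        text = path.read_text().replace("introjection", "unknown_level")
        path.write_text(text)
        with pytest.raises(ValidationError):
            read_cohort(path)

    def test_record_range_validation(self):
        with pytest.raises(ValidationError):
            make_record(vas_pre=101)
        with pytest.raises(ValidationError):
            make_record(age=17)
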