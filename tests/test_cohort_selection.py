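"""Exclusion cascades, precedence and the attrition summary."""

from datetime import date

import pandas as pd
import pytest

from bcclaims.cohort_selection import (
    CASE_REASONS,
    classify_case,
    classify_control,
    index_diagnosis,
    select_cohort,
    selection_summary,
)
from bcclaims.reporting import percent

from conftest import dx_in, dx_out, ins, make_bundle, patient


def _classify(kind, pat, diagnoses=(), fills=(), procedures=(), insurance=None, code_lists=None):
    b = make_bundle([pat], diagnoses, fills, procedures, insurance)
    fn = classify_case if kind == "case" else classify_control
    return fn(b.patients.iloc[0], b.diagnoses, b.fills, b.procedures, b.insurance, code_lists)


class TestIndexDiagnosis:
    def test_earliest_inpatient_c50(self):
        b = make_bundle([patient("p")], [dx_in("p", "C50.4", date(2015, 1, 1)),
                                         dx_in("p", "C50.4", date(2014, 3, 2))])
        assert index_diagnosis(b.diagnoses) == date(2014, 3, 2)

    def test_outpatient_only_gives_no_index(self):
        b = make_bundle([patient("p")], [dx_out("p", "C50.4", 2015, 2)])
        assert index_diagnosis(b.diagnoses) is None

    def test_no_c50(self):
        b = make_bundle([patient("p")], [dx_in("p", "C34.1", date(2015, 1, 1))])
        assert index_diagnosis(b.diagnoses) is None


class TestCaseCascade:
    def test_clean_case_included(self, code_lists):
        out = _classify("case", patient("p"), [dx_in("p", "C50.4", date(2015, 3, 2))],
                        code_lists=code_lists)
        assert (out.status, out.reason, out.index_date) == ("included", "none", date(2015, 3, 2))

    def test_male_with_valid_c50(self, code_lists):
        out = _classify("case", patient("p", sex="male"),
                        [dx_in("p", "C50.4", date(2015, 3, 2))], code_lists=code_lists)
        assert (out.status, out.reason) == ("excluded", "male_sex")

    @pytest.mark.parametrize("idx", [date(2010, 4, 15), date(2020, 2, 1)])
    def test_index_outside_analysis_window(self, code_lists, idx):
        out = _classify("case", patient("p"), [dx_in("p", "C50.4", idx)], code_lists=code_lists)
        assert out.reason == "outside_time_window"

    def test_second_primary_any_time(self, code_lists):
        out = _classify("case", patient("p"),
                        [dx_in("p", "C50.4", date(2015, 3, 2)),
                         dx_in("p", "C34.1", date(2019, 1, 1))], code_lists=code_lists)
        assert out.reason == "secondary_neoplasia"

    def test_non_melanoma_skin_cancer_tolerated(self, code_lists):
        out = _classify("case", patient("p"),
                        [dx_in("p", "C50.4", date(2015, 3, 2)),
                         dx_in("p", "C44.5", date(2016, 1, 1))], code_lists=code_lists)
        assert out.status == "included"

    def test_metastasis_codes_are_not_second_primaries(self, code_lists):
        # C78 within the stage window must NOT trigger the neoplasia rule
        out = _classify("case", patient("p"),
                        [dx_in("p", "C50.4", date(2015, 3, 2)),
                         dx_in("p", "C78.0", date(2015, 5, 1))], code_lists=code_lists)
        assert out.status == "included"

    def test_prior_metastasis(self, code_lists):
        out = _classify("case", patient("p"),
                        [dx_in("p", "C50.4", date(2015, 3, 2)),
                         dx_in("p", "C78.0", date(2014, 6, 1))], code_lists=code_lists)
        assert out.reason == "prior_metastasis"

    def test_short_insurance(self, code_lists):
        out = _classify("case", patient("p"), [dx_in("p", "C50.4", date(2015, 3, 2))],
                        insurance=[ins("p", date(2010, 1, 1), date(2012, 12, 31))],
                        code_lists=code_lists)
        assert out.reason == "insured_too_short"

    def test_death_before_diagnosis(self, code_lists):
        out = _classify("case", patient("p", death=date(2015, 1, 1)),
                        [dx_in("p", "C50.4", date(2015, 3, 2))], code_lists=code_lists)
        assert out.reason == "death_before_diagnosis"

    def test_precedence_earliest_rule_wins(self, code_lists):
        # male + second primary + outpatient-only C50: unreliable C50 first
        out = _classify("case", patient("p", sex="male"),
                        [dx_out("p", "C50.4", 2015, 2), dx_in("p", "C34.1", date(2016, 1, 1))],
                        code_lists=code_lists)
        assert out.reason == "unreliable_c50"
        # male + second primary with valid C50: neoplasia precedes male sex
        out = _classify("case", patient("p", sex="male"),
                        [dx_in("p", "C50.4", date(2015, 3, 2)), dx_in("p", "C34.1", date(2016, 1, 1))],
                        code_lists=code_lists)
        assert out.reason == "secondary_neoplasia"


class TestControlCascade:
    def test_second_primary(self, code_lists):
        out = _classify("control", patient("k", group="control_candidate"),
                        [dx_in("k", "C34.1", date(2015, 1, 1))], code_lists=code_lists)
        assert out.reason == "secondary_neoplasia"

    def test_outpatient_metastasis_run(self, code_lists):
        rows = [dx_out("k", "C78.0", 2015, q) for q in (1, 2, 3)]
        out = _classify("control", patient("k", group="control_candidate"), rows,
                        code_lists=code_lists)
        assert out.reason == "metastasis"

    def test_no_insurance_data(self, code_lists):
        out = _classify("control", patient("k", group="control_candidate"),
                        insurance=[], code_lists=code_lists)
        assert out.reason == "insured_too_short"

    def test_clean_control_eligible(self, code_lists):
        out = _classify("control", patient("k", group="control_candidate"),
                        code_lists=code_lists)
        assert (out.status, out.reason) == ("included", "none")


class TestSelectCohortAndSummary:
    def test_row_order_invariance(self, code_lists):
        pats = [patient("a"), patient("b", sex="male"),
                patient("k", group="control_candidate")]
        dx = [dx_in("a", "C50.4", date(2015, 3, 2)), dx_in("b", "C50.1", date(2016, 1, 1))]
        b1 = make_bundle(pats, dx)
        b2 = make_bundle(list(reversed(pats)), list(reversed(dx)))
        r1 = select_cohort(b1, code_lists)
        r2 = select_cohort(b2, code_lists)
        for x, y in zip(r1, r2):
            pd.testing.assert_frame_equal(x.reset_index(drop=True), y.reset_index(drop=True))

    def test_summary_partitions_the_total(self, code_lists):
        outcomes = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(10)],
            "status": ["excluded"] * 4 + ["included"] * 6,
            "reason": ["male_sex"] * 4 + ["none"] * 6,
            "index_date": [None] * 10,
        })
        summary = selection_summary(outcomes, CASE_REASONS)
        assert summary.loc[summary["row"] == "total", "n"].item() == 10
        body = summary.loc[summary["row"] != "total"]
        assert body["n"].sum() == 10
        assert summary.loc[summary["row"] == "excluded_male_sex", "pct"].item() == 40.0
        assert summary.loc[summary["row"] == "included", "pct"].item() == 60.0

    def test_summary_reproduces_published_attrition_arithmetic(self):
        # worked example on the published candidate counts
        assert percent(27869, 97121) == 28.7
        counts = {"unreliable_c50": 50098, "outside_time_window": 7069,
                  "secondary_neoplasia": 9640, "prior_metastasis": 1487,
                  "insured_too_short": 652, "death_before_diagnosis": 91,
                  "male_sex": 215}
        rows = []
        for reason, n in counts.items():
            rows += [{"patient_id": f"{reason}{i}", "status": "excluded",
                      "reason": reason, "index_date": None} for i in range(n)]
        rows += [{"patient_id": f"inc{i}", "status": "included", "reason": "none",
                  "index_date": None} for i in range(27869)]
        summary = selection_summary(pd.DataFrame(rows), CASE_REASONS)
        assert summary.loc[summary["row"] == "included", "pct"].item() == 28.7
        assert summary.loc[summary["row"] == "excluded_unreliable_c50", "pct"].item() == 51.6
        assert summary["n"].sum() == 2 * 97121  # total row + partition

    def test_empty_outcomes(self):
        summary = selection_summary(pd.DataFrame(columns=["patient_id", "status", "reason", "index_date"]))
        assert summary.loc[summary["row"] == "total", "n"].item() == 0
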