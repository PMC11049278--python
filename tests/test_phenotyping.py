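"""Metastasis-onset criteria, staging, subtype and treatment flags."""

import random
from datetime import date, timedelta

import pytest

from bcclaims.claims_core import ObservationWindow, STUDY_END, STUDY_START
from bcclaims.phenotyping import (
    CodeLists,
    PhenotypeConfig,
    assign_stage,
    assign_subtype,
    metastasis_onset,
    treatment_flags,
)

from conftest import dx_in, dx_out, fill, make_bundle, patient, proc

WINDOW = ObservationWindow(STUDY_START, STUDY_END)


def _frames(diagnoses=(), fills=(), procedures=()):
    b = make_bundle([patient("p")], diagnoses, fills, procedures)
    return b.diagnoses, b.fills, b.procedures


def onset(code_lists, diagnoses=(), fills=(), procedures=(), **cfg):
    dx, f, pr = _frames(diagnoses, fills, procedures)
    return metastasis_onset(dx, f, pr, code_lists, PhenotypeConfig(**cfg))


class TestMetastasisOnset:
    def test_direct_inpatient(self, code_lists):
        assert onset(code_lists, [dx_in("p", "C78.0", date(2016, 2, 1))]) == (
            date(2016, 2, 1), "direct_icd")

    def test_axillary_and_nos_nodes_never_count(self, code_lists):
        assert onset(code_lists, [dx_in("p", "C77.3", date(2016, 2, 1)),
                                  dx_in("p", "C77.9", date(2016, 3, 1))]) is None

    def test_outpatient_needs_three_consecutive_quarters(self, code_lists):
        two = [dx_out("p", "C78.0", 2015, 1), dx_out("p", "C78.0", 2015, 2)]
        assert onset(code_lists, two) is None
        three = two + [dx_out("p", "C78.0", 2015, 3)]
        # onset = midpoint of the first quarter of the run
        assert onset(code_lists, three) == (date(2015, 2, 15), "direct_icd")
        # non-consecutive quarters never fire
        gap = [dx_out("p", "C78.0", 2015, 1), dx_out("p", "C78.0", 2015, 3),
               dx_out("p", "C78.0", 2016, 1)]
        assert onset(code_lists, gap) is None

    def test_outpatient_m2q_convention_configurable(self, code_lists):
        two = [dx_out("p", "C78.0", 2015, 1), dx_out("p", "C78.0", 2015, 2)]
        assert onset(code_lists, two, outpatient_consecutive_quarters=2) == (
            date(2015, 2, 15), "direct_icd")

    def test_chemo_fifth_distinct_quarter(self, code_lists):
        # fills in 2015Q1-Q4 and 2016Q1: the 5th distinct quarter is 2016Q1
        fills = [fill("p", "L01CA04", date(2015, 3 * q - 2, 10)) for q in (1, 2, 3, 4)]
        fills.append(fill("p", "L01CA04", date(2016, 1, 20)))
        assert onset(code_lists, fills=fills) == (date(2016, 2, 15), "chemo_5q")
        # four quarters are not enough
        assert onset(code_lists, fills=fills[:-1]) is None

    def test_chemo_quarters_need_not_be_consecutive(self, code_lists):
        fills = [fill("p", "L01CA04", date(y, m, 5))
                 for y, m in ((2014, 1), (2014, 8), (2015, 2), (2015, 11), (2016, 7))]
        assert onset(code_lists, fills=fills) == (date(2016, 8, 15), "chemo_5q")

    def test_her2_seventh_distinct_quarter(self, code_lists):
        fills = [fill("p", "L01XC03", date(2014 + k // 4, 3 * (k % 4) + 1, 10))
                 for k in range(7)]  # 2014Q1..Q4, 2015Q1..Q3
        d, crit = onset(code_lists, fills=fills)
        assert crit == "her2_7q"
        assert d == date(2015, 8, 15)  # 7th distinct quarter is 2015Q3
        assert onset(code_lists, fills=fills[:-1]) is None
        # HER2 antibodies are in ATC L01 but never count as chemotherapy
        assert onset(code_lists, fills=fills[:4]) is None

    def test_met_defining_first_quarter(self, code_lists):
        fills = [fill("p", "V10XX03", date(2015, 5, 2)), fill("p", "V10XX03", date(2015, 8, 2))]
        assert onset(code_lists, fills=fills) == (date(2015, 5, 16), "met_medication_2q")
        assert onset(code_lists, fills=fills[:1]) is None

    def test_histology_date_exact_and_earliest_wins(self, code_lists):
        res = onset(
            code_lists,
            diagnoses=[dx_in("p", "C78.0", date(2016, 2, 1))],
            procedures=[proc("p", "1-563", date(2015, 11, 20))],
        )
        assert res == (date(2015, 11, 20), "histology")

    def test_no_events(self, code_lists):
        assert onset(code_lists) is None

    def test_order_invariance_and_monotonicity(self, code_lists):
        events = [dx_in("p", "C78.0", date(2016, 2, 1)),
                  dx_in("p", "C79.5", date(2015, 6, 1)),
                  dx_out("p", "C78.1", 2014, 2)]
        rng = random.Random(0)
        base = None
        for _ in range(5):
            rng.shuffle(events)
            res = onset(code_lists, events)
            base = base or res
            assert res == base
        # adding an earlier event can only advance the onset
        more = events + [dx_in("p", "C78.7", date(2013, 1, 5))]
        assert onset(code_lists, more)[0] <= base[0]


class TestStage:
    idx = date(2015, 3, 2)

    def test_metastasis_in_window_is_stage_c(self):
        assert assign_stage(self.idx + timedelta(days=100), [], self.idx) == "C"
        # two-sided window: onset shortly before the index is still primary
        assert assign_stage(self.idx - timedelta(days=100), [], self.idx) == "C"
        assert assign_stage(self.idx - timedelta(days=183), [], self.idx) == "A"
        assert assign_stage(self.idx + timedelta(days=183), [], self.idx) == "C"
        assert assign_stage(self.idx + timedelta(days=184), [], self.idx) == "A"

    def test_axillary_in_window_is_stage_b(self):
        assert assign_stage(None, [self.idx + timedelta(days=30)], self.idx) == "B"
        assert assign_stage(None, [self.idx + timedelta(days=200)], self.idx) == "A"
        assert assign_stage(None, [], self.idx) == "A"

    def test_metastasis_precedes_axillary(self):
        assert assign_stage(self.idx + timedelta(days=50),
                            [self.idx + timedelta(days=30)], self.idx) == "C"


class TestSubtype:
    idx = date(2015, 3, 2)

    def _subtype(self, code_lists, fills_rows):
        _, f, _ = _frames(fills=fills_rows)
        return assign_subtype(f, self.idx, WINDOW, code_lists)

    def test_endocrine_after_index(self, code_lists):
        assert self._subtype(code_lists, [fill("p", "L02BA01", self.idx + timedelta(days=60))]) == "HR+/HER2-"

    def test_gnrh_alone_is_not_hr_positive(self, code_lists):
        assert self._subtype(code_lists, [fill("p", "L02AE03", self.idx + timedelta(days=60))]) == "HR-/HER2-"

    def test_trastuzumab_plus_letrozole(self, code_lists):
        rows = [fill("p", "L01XC03", self.idx + timedelta(days=30)),
                fill("p", "L02BG04", self.idx + timedelta(days=40))]
        assert self._subtype(code_lists, rows) == "HR+/HER2+"

    def test_pre_index_fills_ignored(self, code_lists):
        assert self._subtype(code_lists, [fill("p", "L02BA01", self.idx - timedelta(days=10))]) == "HR-/HER2-"
        # perturbation: adding pre-index fills never changes the call
        rows = [fill("p", "L01XC03", self.idx + timedelta(days=30))]
        with_pre = rows + [fill("p", "L02BA01", self.idx - timedelta(days=400))]
        assert self._subtype(code_lists, rows) == self._subtype(code_lists, with_pre) == "HR-/HER2+"


class TestTreatmentFlags:
    idx = date(2015, 3, 2)

    def _flags(self, code_lists, fills_rows=(), proc_rows=()):
        _, f, pr = _frames(fills=fills_rows, procedures=proc_rows)
        return treatment_flags(pr, f, self.idx, WINDOW, code_lists)

    def test_surgery_and_radiation(self, code_lists):
        flags = self._flags(code_lists, proc_rows=[proc("p", "5-870", self.idx + timedelta(days=10)),
                                                   proc("p", "8-520", self.idx + timedelta(days=40))])
        assert flags == (True, True, False)

    def test_no_events_after_index(self, code_lists):
        assert self._flags(code_lists, proc_rows=[proc("p", "5-870", self.idx - timedelta(days=10))]) == (
            False, False, False)

    def test_chemo_sets_systemic_but_endocrine_does_not(self, code_lists):
        assert self._flags(code_lists, fills_rows=[fill("p", "L01CA04", self.idx + timedelta(days=20))])[2]
        assert not self._flags(code_lists, fills_rows=[fill("p", "L02BA01", self.idx + timedelta(days=20))])[2]


def test_code_list_overlap_rejected():
    with pytest.raises(Exception):
        CodeLists(endocrine_atc=frozenset({"L02"}), gnrh_atc=frozenset({"L02AE"}))
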