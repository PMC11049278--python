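"""Kaplan-Meier estimation, Greenwood errors, log-rank, record building."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from bcclaims.claims_core import ClaimsError
from bcclaims.matching import MatchSet
from bcclaims.survival import (
    drfs_records,
    km_estimate,
    logrank,
    os_records,
    survival_at,
)

from conftest import make_bundle, patient


def records(times, events, group="g", stratum="s"):
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(times))],
        "group": group, "stratum": stratum,
        "time_days": times, "event": events,
    })


class TestKaplanMeier:
    def test_hand_product_limit_example(self):
        # 3 subjects: event at 1, censored at 2, event at 3
        curve = km_estimate(records([1, 2, 3], [True, False, True]))
        assert list(curve.times) == [1, 3]
        assert curve.survival[0] == pytest.approx(2 / 3)
        assert curve.survival[1] == pytest.approx(0.0)
        # Greenwood at t=1: S^2 * d/(n(n-d)) = (2/3)^2 * 1/6
        assert curve.se[0] == pytest.approx(np.sqrt((2 / 3) ** 2 / 6))
        assert curve.se[1] == 0.0  # degenerate at S=0

    def test_all_censored_is_flat_one(self):
        curve = km_estimate(records([5, 8, 13], [False] * 3))
        assert len(curve.times) == 0
        assert survival_at(curve, 10).estimate == 1.0

    def test_single_subject_event(self):
        curve = km_estimate(records([5], [True]))
        assert survival_at(curve, 5).estimate == 0.0

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 400, size=150)
        curve = km_estimate(records(list(t), [True] * 150))
        for h in (50, 100, 250):
            empirical = np.mean(t > h)
            assert survival_at(curve, h).estimate == pytest.approx(empirical)

    def test_moving_late_censoring_later_changes_nothing(self):
        # a subject censored after the last event contributes only
        # at-risk time; delaying that censoring leaves the curve intact
        base = km_estimate(records([1, 2, 3, 5], [True, False, True, False]))
        moved = km_estimate(records([1, 2, 3, 50], [True, False, True, False]))
        np.testing.assert_allclose(base.survival, moved.survival)
        np.testing.assert_allclose(base.se, moved.se)
        assert list(base.times) == list(moved.times)

    def test_empty_input_rejected(self):
        with pytest.raises(ClaimsError):
            km_estimate(records([], []))


class TestSurvivalAt:
    curve = km_estimate(records([1, 2, 3], [True, False, True]))

    def test_step_function_between_events(self):
        assert survival_at(self.curve, 2).estimate == pytest.approx(2 / 3)

    def test_at_zero(self):
        at = survival_at(self.curve, 0)
        assert (at.estimate, at.se, at.beyond_follow_up) == (1.0, 0.0, False)

    def test_beyond_follow_up_is_flagged(self):
        at = survival_at(self.curve, 10)
        assert at.beyond_follow_up
        assert at.estimate == pytest.approx(0.0)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        a = records([1, 2, 3, 4], [True, True, False, True], group="a")
        b = a.copy()
        b["group"] = "b"
        res = logrank(pd.concat([a, b]), "group")
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_hand_computed_two_group_statistic(self):
        # group 1 events at 1,2,3; group 2 at 10,11,12; no censoring.
        # By hand: O1=3, E1=3/6+2/5+1/4=1.15, V=0.25+0.24+0.1875=0.6775,
        # chi2=(3-1.15)^2/0.6775
        recs = pd.concat([
            records([1, 2, 3], [True] * 3, group="g1"),
            records([10, 11, 12], [True] * 3, group="g2"),
        ])
        res = logrank(recs, "group")
        assert res.chi_square == pytest.approx((3 - 1.15) ** 2 / 0.6775, rel=1e-10)

    def test_three_groups_df(self):
        recs = pd.concat([
            records([1, 2], [True, True], group="a"),
            records([3, 4], [True, True], group="b"),
            records([5, 6], [True, True], group="c"),
        ])
        res = logrank(recs, "group")
        assert res.df == 2
        assert 0 < res.p_value <= 1

    def test_relabeling_invariance(self):
        recs = pd.concat([
            records([1, 5, 9], [True, True, False], group="x"),
            records([2, 6, 20], [True, False, True], group="y"),
        ])
        swapped = recs.copy()
        swapped["group"] = swapped["group"].map({"x": "y", "y": "x"})
        assert logrank(recs, "group").chi_square == pytest.approx(
            logrank(swapped, "group").chi_square)

    def test_single_group_rejected(self):
        with pytest.raises(ClaimsError):
            logrank(records([1, 2], [True, True]), "group")


def _phenotypes(rows):
    return pd.DataFrame(rows, columns=[
        "patient_id", "index_date", "stage", "subtype", "met_onset",
        "met_criterion", "surgery", "radiation", "systemic_therapy"])


def _phenorow(pid, idx, stage="A", subtype="HR+/HER2-", met=None):
    return {"patient_id": pid, "index_date": idx, "stage": stage, "subtype": subtype,
            "met_onset": met, "met_criterion": "none", "surgery": True,
            "radiation": False, "systemic_therapy": False}


class TestRecordBuilding:
    def test_os_case_times_and_events(self):
        bundle = make_bundle([
            patient("a", death=date(2018, 1, 1)), patient("b"),
            patient("k1", death=date(2016, 1, 1), group="control_candidate"),
            patient("k2", group="control_candidate"),
        ])
        phen = _phenotypes([_phenorow("a", date(2015, 1, 1)), _phenorow("b", date(2015, 1, 1))])
        sets = [MatchSet("a", ("k1", "k2"), (0, 0))]
        recs = os_records(phen, sets, bundle).set_index("patient_id")
        assert (recs.loc["a", "time_days"], recs.loc["a", "event"]) == (1096, True)
        assert (recs.loc["b", "time_days"], recs.loc["b", "event"]) == (2191, False)
        # control clock starts at the matched case's index date and the
        # control inherits the case's stratum
        assert (recs.loc["k1", "time_days"], recs.loc["k1", "event"]) == (365, True)
        assert recs.loc["k1", "stratum"] == "A|HR+/HER2-"
        assert recs.loc["k2", "event"] == False  # noqa: E712

    def test_os_death_after_study_end_is_censored(self):
        bundle = make_bundle([patient("a", death=date(2021, 8, 1))])
        phen = _phenotypes([_phenorow("a", date(2015, 1, 1))])
        recs = os_records(phen, [], bundle)
        assert (recs.loc[0, "time_days"], recs.loc[0, "event"]) == (2191, False)

    def test_control_caliper_violation_raises(self):
        bundle = make_bundle([
            patient("a"), patient("k", death=date(2014, 1, 1), group="control_candidate"),
        ])
        phen = _phenotypes([_phenorow("a", date(2015, 1, 1))])
        with pytest.raises(ClaimsError, match="caliper"):
            os_records(phen, [MatchSet("a", ("k",), (0,))], bundle)

    def test_drfs_event_and_death_censoring(self):
        bundle = make_bundle([patient("a"), patient("b", death=date(2016, 2, 5))])
        phen = _phenotypes([
            _phenorow("a", date(2015, 1, 1), met=date(2016, 12, 1)),
            _phenorow("b", date(2015, 1, 1)),
        ])
        recs = drfs_records(phen, bundle).set_index("patient_id")
        assert (recs.loc["a", "time_days"], recs.loc["a", "event"]) == (700, True)
        assert (recs.loc["b", "time_days"], recs.loc["b", "event"]) == (400, False)

    def test_drfs_rejects_stage_c(self):
        bundle = make_bundle([patient("a")])
        phen = _phenotypes([_phenorow("a", date(2015, 1, 1), stage="C")])
        with pytest.raises(ClaimsError, match="stage C"):
            drfs_records(phen, bundle)


def test_km_recovers_exponential_survival():
    """One-seed parameter recovery: S(5y) near exp(-5*lambda)."""
    rng = np.random.default_rng(123)
    lam = 0.14  # per year
    n = 2000
    t_event = rng.exponential(1 / lam, n) * 365.25
    t_cens = rng.uniform(0, 11 * 365.25, n)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    curve = km_estimate(records(list(time), list(event)))
    at = survival_at(curve, 5 * 365.25)
    assert abs(at.estimate - np.exp(-5 * lam)) < 3 * at.se
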