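"""Matched time-to-event analysis: OS and DRFS records, Kaplan-Meier
curves with Greenwood standard errors, and log-rank comparisons.

Overall survival (OS) runs from the index diagnosis (first inpatient C50
coding) to death; follow-up is administratively censored at the study end
(2020-12-31) even when later deaths are known, mirroring the
observation-window truncation.  Matched controls have no diagnosis, so
their clock starts at their matched case's index date — the matching
caliper guarantees they were alive and insured then, hence non-negative
times — and they inherit the case's stage/subtype stratum for
subtype-specific comparisons.  An alternative convention (control
follow-up from the study start) is available behind a switch.

Distant recurrence-free survival (DRFS) runs from the index diagnosis to
the first distant metastasis and is defined only for stages A and B
(stage C is metastatic at baseline).  Death without metastasis censors;
no competing-risk treatment.

Estimation is the product-limit (Kaplan-Meier) estimator with the
Greenwood variance  Var[S(t)] = S(t)^2 * sum_{t_i<=t} d_i/(n_i(n_i-d_i)),
fitted via lifelines; group comparison is the unweighted log-rank test
against a chi-square with (groups - 1) degrees of freedom.
"""

from __future__ import annotations

import dataclasses
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .claims_core import STUDY_END, ClaimsBundle, ClaimsError, observation_window
from .matching import MatchSet

__all__ = [
    "KMCurve",
    "LogRankResult",
    "SurvivalAt",
    "os_records",
    "drfs_records",
    "km_estimate",
    "survival_at",
    "logrank",
]

RECORD_COLUMNS = ["patient_id", "group", "stratum", "time_days", "event"]


@dataclasses.dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate at the distinct event times.

    ``survival[i]`` is S(times[i]); ``se`` the Greenwood standard error
    (0 where the curve has dropped to exactly 0, where Greenwood's formula
    degenerates).  ``max_follow_up`` is the largest observed duration,
    event or censored.
    """

    times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    se: np.ndarray
    max_follow_up: float

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ClaimsError("KM event times must be strictly increasing")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ClaimsError("KM survival must be non-increasing")


@dataclasses.dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclasses.dataclass(frozen=True)
class SurvivalAt:
    estimate: float
    se: float
    beyond_follow_up: bool = False


# ---------------------------------------------------------------------------
# Record construction
# ---------------------------------------------------------------------------


def _case_record(pid, index_date, death_date, stratum) -> dict:
    window = observation_window(death_date)
    time = (window.end - index_date).days
    event = death_date is not None and death_date <= STUDY_END
    if time < 0:
        raise ClaimsError(f"case {pid!r}: negative follow-up time {time}")
    return {"patient_id": pid, "group": "case", "stratum": stratum,
            "time_days": time, "event": bool(event)}


def os_records(
    phenotypes: pd.DataFrame,
    matchsets: Sequence[MatchSet],
    bundle: ClaimsBundle,
    control_index: str = "case_index",
) -> pd.DataFrame:
    """OS records for cases and their matched controls.

    ``control_index`` selects the control follow-up origin:
    ``"case_index"`` (default; the matched case's diagnosis date) or
    ``"study_start"``.  Controls inherit their case's (stage, subtype)
    stratum.  Negative control times indicate a caliper violation and
    raise.
    """
    if control_index not in ("case_index", "study_start"):
        raise ClaimsError(f"unknown control_index mode {control_index!r}")
    death = dict(zip(bundle.patients["patient_id"], bundle.patients["death_date"]))
    pheno = phenotypes.set_index("patient_id")
    rows = []
    for pid, row in pheno.iterrows():
        stratum = f"{row['stage']}|{row['subtype']}"
        rows.append(_case_record(pid, row["index_date"], death.get(pid), stratum))
    for ms in matchsets:
        case = pheno.loc[ms.case_id]
        origin = case["index_date"] if control_index == "case_index" else date(2010, 1, 1)
        stratum = f"{case['stage']}|{case['subtype']}"
        for cid in ms.control_ids:
            dd = death.get(cid)
            window = observation_window(dd)
            time = (window.end - origin).days
            if time < 0:
                raise ClaimsError(
                    f"control {cid!r} has negative follow-up from case "
                    f"{ms.case_id!r} index; matching caliper violated"
                )
            rows.append({
                "patient_id": cid, "group": "control", "stratum": stratum,
                "time_days": time,
                "event": bool(dd is not None and dd <= STUDY_END),
            })
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def drfs_records(phenotypes: pd.DataFrame, bundle: ClaimsBundle) -> pd.DataFrame:
    """DRFS records for stage A/B cases; metastasis is the event, death
    censors.  Raises if a stage-C row is passed in."""
    if (phenotypes["stage"] == "C").any():
        bad = phenotypes.loc[phenotypes["stage"] == "C", "patient_id"].iloc[0]
        raise ClaimsError(
            f"stage C patient {bad!r} has no DRFS (metastatic at baseline); "
            "filter to stages A and B first"
        )
    death = dict(zip(bundle.patients["patient_id"], bundle.patients["death_date"]))
    rows = []
    for _, row in phenotypes.iterrows():
        pid = row["patient_id"]
        stratum = f"{row['stage']}|{row['subtype']}"
        met = row["met_onset"]
        if met is not None and not pd.isna(met):
            time = (met - row["index_date"]).days
            event = True
        else:
            window = observation_window(death.get(pid))
            time = (window.end - row["index_date"]).days
            event = False
        if time < 0:
            raise ClaimsError(f"patient {pid!r}: negative DRFS time {time}")
        rows.append({"patient_id": pid, "group": "case", "stratum": stratum,
                     "time_days": time, "event": event})
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit curve with Greenwood standard errors."""
    if len(records) == 0:
        raise ClaimsError("cannot estimate a survival curve from no records")
    durations = records["time_days"].to_numpy(dtype=float)
    events = records["event"].to_numpy(dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    table = kmf.event_table
    ev = table.loc[table["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    n_at_risk = ev["at_risk"].to_numpy(dtype=float)
    n_events = ev["observed"].to_numpy(dtype=float)
    survival = kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_events / (n_at_risk * (n_at_risk - n_events))
        var = survival**2 * np.cumsum(terms)
    se = np.sqrt(np.where(survival > 0, var, 0.0))
    return KMCurve(
        times=times,
        n_at_risk=n_at_risk.astype(int),
        n_events=n_events.astype(int),
        survival=survival,
        se=se,
        max_follow_up=float(durations.max()),
    )


def survival_at(curve: KMCurve, horizon_days: float) -> SurvivalAt:
    """Step-function evaluation of the curve at a horizon.

    Beyond the last observed follow-up the curve carries its last value
    forward, flagged via ``beyond_follow_up``.
    """
    if horizon_days < 0:
        raise ClaimsError("horizon must be non-negative")
    idx = np.searchsorted(curve.times, horizon_days, side="right") - 1
    if idx < 0:
        est, se = 1.0, 0.0
    else:
        est, se = float(curve.survival[idx]), float(curve.se[idx])
    return SurvivalAt(est, se, beyond_follow_up=horizon_days > curve.max_follow_up)


def logrank(records: pd.DataFrame, grouping: str = "group") -> LogRankResult:
    """Unweighted log-rank test across the groups of ``records[grouping]``."""
    groups = records[grouping]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ClaimsError("log-rank needs at least two groups")
    counts = groups.value_counts()
    if (counts < 1).any() or len(records) == 0:
        raise ClaimsError("every group needs at least one record")
    res = multivariate_logrank_test(
        records["time_days"], groups, records["event"]
    )
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(labels) - 1,
        p_value=float(res.p_value),
    )
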