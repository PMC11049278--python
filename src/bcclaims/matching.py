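"""Optimal 1:k case-control matching on birth year with a consistency caliper.

Each case must be paired with exactly ``ratio`` distinct controls (default
1:2); every control is used at most once; the total absolute birth-year
difference over all pairs is minimized.  A "no exclusion before diagnosis"
caliper forbids pairing a case with a control who died or whose insurance
ended on/before the case's diagnosis date — such a control could never
have been observed as a comparable subject from the case's index date on.

The problem is the classic minimum-cost bipartite b-matching.  It is
solved exactly as a rectangular linear assignment problem: each case row
is replicated ``ratio`` times, forbidden pairs cost infinity, and the
Jonker-Volgenant solver (``scipy.optimize.linear_sum_assignment``, a
shortest-augmenting-path network-flow algorithm) returns the optimum.
Ties between equal-cost optima are broken lexicographically by
(case position, control position) through an integer rank perturbation
that is provably too small to disturb optimality.

Very large cohorts can be partitioned round-robin into ``n_split``
independent sub-problems (historically used to fit in memory); per-split
optimality then holds but the combined cost may exceed the unsplit
optimum.
"""

from __future__ import annotations

import dataclasses
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .claims_core import ClaimsError

__all__ = [
    "MatchProblem",
    "MatchSet",
    "MatchingError",
    "admissible",
    "match_cohort_id",
    "optimal_match",
    "validate_matching",
    "matchsets_frame",
]


class MatchingError(ClaimsError):
    """Infeasible or invalid matching."""


@dataclasses.dataclass(frozen=True)
class MatchProblem:
    """Cases and admissible-control data for one matching run.

    ``cases``: DataFrame(case_id, birth_year, index_date);
    ``controls``: DataFrame(control_id, birth_year, death_date,
    insurance_end) where death_date/insurance_end may be None (treated as
    "never", i.e. always admissible on that criterion).
    """

    cases: pd.DataFrame
    controls: pd.DataFrame
    ratio: int = 2
    n_split: int = 1

    def __post_init__(self):
        if self.ratio < 1 or self.n_split < 1:
            raise MatchingError("ratio and n_split must be positive")


@dataclasses.dataclass(frozen=True)
class MatchSet:
    case_id: str
    control_ids: tuple[str, ...]
    age_diffs: tuple[int, ...]


def admissible(
    death_date: date | None, insurance_end: date | None, case_index_date: date
) -> bool:
    """Caliper: the control must outlive (and stay insured past) the
    case's diagnosis date."""
    if death_date is not None and death_date <= case_index_date:
        return False
    if insurance_end is not None and insurance_end <= case_index_date:
        return False
    return True


def match_cohort_id(sequential_id: int, n_split: int) -> int:
    """Round-robin split cohort for a consecutively assigned id."""
    return sequential_id % n_split


def _solve_split(
    cases: pd.DataFrame, controls: pd.DataFrame, ratio: int, split_label: int
) -> list[MatchSet]:
    n_cases, n_controls = len(cases), len(controls)
    if n_cases == 0:
        return []
    if ratio * n_cases > n_controls:
        raise MatchingError(
            f"split {split_label}: need {ratio * n_cases} controls for "
            f"{n_cases} cases, only {n_controls} available"
        )
    case_years = cases["birth_year"].to_numpy(dtype=np.int64)
    ctrl_years = controls["birth_year"].to_numpy(dtype=np.int64)
    cost = np.abs(case_years[:, None] - ctrl_years[None, :]).astype(float)

    ok = np.ones((n_cases, n_controls), dtype=bool)
    for j, (_, ctrl) in enumerate(controls.iterrows()):
        dd, ie = ctrl["death_date"], ctrl["insurance_end"]
        for i, (_, case) in enumerate(cases.iterrows()):
            ok[i, j] = admissible(dd, ie, case["index_date"])
    cost[~ok] = np.inf

    # replicate case rows `ratio` times; lexicographic tie-break via a rank
    # perturbation scaled so its total can never offset one unit of cost
    big = np.repeat(cost, ratio, axis=0)
    n_rows = big.shape[0]
    ranks = np.arange(n_rows * n_controls, dtype=float).reshape(n_rows, n_controls)
    eps = 1.0 / (n_rows * n_controls * n_rows + 1.0)
    perturbed = big * 1.0 + ranks * eps
    try:
        row_ind, col_ind = linear_sum_assignment(perturbed)
    except ValueError as exc:  # scipy: "cost matrix is infeasible"
        deficit = _feasibility_deficit(cost, ratio)
        raise MatchingError(
            f"split {split_label}: caliper leaves a deficit of {deficit} "
            f"control slots"
        ) from exc

    per_case: dict[int, list[int]] = {}
    for r, c in zip(row_ind, col_ind):
        per_case.setdefault(r // ratio, []).append(int(c))
    out = []
    case_ids = cases["case_id"].tolist()
    ctrl_ids = controls["control_id"].tolist()
    for i in sorted(per_case):
        cols = sorted(per_case[i])
        out.append(
            MatchSet(
                case_id=case_ids[i],
                control_ids=tuple(ctrl_ids[c] for c in cols),
                age_diffs=tuple(int(abs(case_years[i] - ctrl_years[c])) for c in cols),
            )
        )
    return out


def _feasibility_deficit(cost: np.ndarray, ratio: int) -> int:
    """Unfillable control slots when the caliper makes a split infeasible."""
    finite = np.isfinite(cost)
    huge = np.where(finite, cost, 1e12)
    big = np.repeat(huge, ratio, axis=0)
    row_ind, col_ind = linear_sum_assignment(big)
    bad = sum(1 for r, c in zip(row_ind, col_ind) if not finite[r // ratio, c])
    return bad + (big.shape[0] - len(row_ind))


def optimal_match(problem: MatchProblem) -> list[MatchSet]:
    """Globally (per split) optimal 1:ratio matching.

    Inputs are canonicalized by sorting on ids, so permuting input row
    order changes neither the total cost nor the returned sets.
    """
    cases = problem.cases.sort_values("case_id").reset_index(drop=True)
    controls = problem.controls.sort_values("control_id").reset_index(drop=True)
    if problem.n_split == 1:
        return _solve_split(cases, controls, problem.ratio, 0)
    # consecutive sequential ids: cases first, then controls
    out: list[MatchSet] = []
    case_split = (np.arange(1, len(cases) + 1) % problem.n_split)
    ctrl_split = (np.arange(len(cases) + 1, len(cases) + len(controls) + 1) % problem.n_split)
    for s in range(problem.n_split):
        out.extend(
            _solve_split(
                cases.loc[case_split == s].reset_index(drop=True),
                controls.loc[ctrl_split == s].reset_index(drop=True),
                problem.ratio,
                s,
            )
        )
    return sorted(out, key=lambda m: m.case_id)


def validate_matching(matchsets: Sequence[MatchSet], problem: MatchProblem) -> dict:
    """Check structural validity; return diagnostics.

    Asserts control uniqueness, exact ratio per case and admissibility of
    every pair; returns total cost and an age-difference histogram.
    Raises :class:`MatchingError` listing offending pairs otherwise.
    """
    controls = problem.controls.set_index("control_id")
    cases = problem.cases.set_index("case_id")
    seen: dict[str, str] = {}
    violations = []
    hist: dict[int, int] = {}
    total = 0
    for ms in matchsets:
        if len(set(ms.control_ids)) != problem.ratio:
            violations.append(f"case {ms.case_id}: expected {problem.ratio} distinct controls")
        case = cases.loc[ms.case_id]
        for cid, diff in zip(ms.control_ids, ms.age_diffs):
            if cid in seen:
                violations.append(f"control {cid} reused (cases {seen[cid]}, {ms.case_id})")
            seen[cid] = ms.case_id
            ctrl = controls.loc[cid]
            if not admissible(ctrl["death_date"], ctrl["insurance_end"], case["index_date"]):
                violations.append(f"pair ({ms.case_id}, {cid}) violates the caliper")
            true_diff = int(abs(int(case["birth_year"]) - int(ctrl["birth_year"])))
            if true_diff != diff:
                violations.append(f"pair ({ms.case_id}, {cid}): age_diff {diff} != {true_diff}")
            hist[diff] = hist.get(diff, 0) + 1
            total += diff
    if violations:
        raise MatchingError("; ".join(violations))
    return {
        "n_matchsets": len(matchsets),
        "n_pairs": sum(len(m.control_ids) for m in matchsets),
        "total_cost": total,
        "age_diff_histogram": dict(sorted(hist.items())),
    }


def matchsets_frame(matchsets: Sequence[MatchSet]) -> pd.DataFrame:
    """Long-form (case_id, control_id, age_diff) table for export."""
    rows = [
        {"case_id": m.case_id, "control_id": c, "age_diff": d}
        for m in matchsets
        for c, d in zip(m.control_ids, m.age_diffs)
    ]
    return pd.DataFrame(rows, columns=["case_id", "control_id", "age_diff"])
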