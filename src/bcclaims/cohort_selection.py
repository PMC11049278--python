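"""Inclusion/exclusion cascades for case and control candidates.

Each candidate receives exactly one outcome: included, or excluded with a
single reason code.  When several rules fire, the earliest rule in the
fixed precedence order wins, which makes the resulting attrition table a
partition of the candidate pool.

Case precedence: unreliable C50 (no inpatient C50 coding) -> index
diagnosis outside the analysis window -> secondary neoplasia -> distant
metastasis at least 6 months before the index -> insured under 40% of the
observation period -> death before the index -> male sex.

Control precedence: secondary neoplasia -> distant metastasis during the
observation period -> missing/short insurance -> male sex.  Eligible
controls are finalized only by matching (which may still mark them
unmatched).

"Secondary neoplasia" means a second primary malignancy: any C-chapter
ICD code except breast cancer itself (C50), non-melanoma skin cancer
(C44) and the metastasis codes C77-C79 (these encode secondary spread of
an existing tumor, handled by the metastasis rules, not a new primary).
An outpatient neoplasia code needs confirmation in two distinct calendar
quarters (M2Q-style); a single inpatient coding suffices.
"""

from __future__ import annotations

import dataclasses
from datetime import date, timedelta
from typing import Iterable

import pandas as pd

from .claims_core import (
    ClaimsBundle,
    Quarter,
    insurance_coverage_fraction,
    observation_window,
)
from .phenotyping import CodeLists, PhenotypeConfig, metastasis_onset

__all__ = [
    "CASE_REASONS",
    "CONTROL_REASONS",
    "SelectionConfig",
    "ExclusionOutcome",
    "index_diagnosis",
    "classify_case",
    "classify_control",
    "select_cohort",
    "selection_summary",
]

#: Exclusion reasons in precedence order (the attrition-table row order).
CASE_REASONS = (
    "unreliable_c50",
    "outside_time_window",
    "secondary_neoplasia",
    "prior_metastasis",
    "insured_too_short",
    "death_before_diagnosis",
    "male_sex",
)
CONTROL_REASONS = ("secondary_neoplasia", "metastasis", "insured_too_short", "male_sex", "unmatched")


@dataclasses.dataclass(frozen=True)
class SelectionConfig:
    coverage_threshold: float = 0.40
    index_window_start: date = date(2010, 7, 1)
    index_window_end: date = date(2019, 12, 31)
    prior_met_days: int = 183
    #: outpatient quarters needed to confirm a secondary-neoplasia code
    neoplasia_outpatient_quarters: int = 2
    #: ICD prefixes that never count as a second primary
    neoplasia_excluded_prefixes: frozenset[str] = frozenset({"C44", "C50", "C77", "C78", "C79"})


@dataclasses.dataclass(frozen=True)
class ExclusionOutcome:
    patient_id: str
    status: str  # included | excluded
    reason: str  # a CASE_REASONS/CONTROL_REASONS member, or "none"
    index_date: date | None = None


def index_diagnosis(diagnoses: pd.DataFrame) -> date | None:
    """Index date: earliest *inpatient* C50 coding; outpatient C50 is
    deemed unreliable and never sets the index."""
    dates = [
        row["date"]
        for _, row in diagnoses.iterrows()
        if row["setting"] == "inpatient" and str(row["icd_code"]).startswith("C50")
    ]
    return min(dates) if dates else None


def _has_secondary_neoplasia(diagnoses: pd.DataFrame, config: SelectionConfig) -> bool:
    """Second primary malignancy, validated inpatient-once or M2Q."""
    outpatient_quarters: dict[str, set[Quarter]] = {}
    for _, row in diagnoses.iterrows():
        code = str(row["icd_code"])
        if not code.startswith("C"):
            continue
        if any(code.startswith(p) for p in config.neoplasia_excluded_prefixes):
            continue
        if row["setting"] == "inpatient":
            return True
        outpatient_quarters.setdefault(code[:3], set()).add(
            Quarter(int(row["quarter_year"]), int(row["quarter_index"]))
        )
    return any(
        len(qs) >= config.neoplasia_outpatient_quarters
        for qs in outpatient_quarters.values()
    )


def _coverage(insurance: pd.DataFrame, death_date: date | None) -> float:
    try:
        window = observation_window(death_date)
    except Exception:
        return 0.0
    periods = [
        (row["start_date"], row["end_date"]) for _, row in insurance.iterrows()
    ]
    return insurance_coverage_fraction(periods, window)


def classify_case(
    patient: pd.Series,
    diagnoses: pd.DataFrame,
    fills: pd.DataFrame,
    procedures: pd.DataFrame,
    insurance: pd.DataFrame,
    code_lists: CodeLists,
    config: SelectionConfig = SelectionConfig(),
    phenotype_config: PhenotypeConfig = PhenotypeConfig(),
) -> ExclusionOutcome:
    """Apply the case cascade to one candidate; always classifiable."""
    pid = patient["patient_id"]
    index = index_diagnosis(diagnoses)
    if index is None:
        return ExclusionOutcome(pid, "excluded", "unreliable_c50")
    if not config.index_window_start <= index <= config.index_window_end:
        return ExclusionOutcome(pid, "excluded", "outside_time_window", index)
    if _has_secondary_neoplasia(diagnoses, config):
        return ExclusionOutcome(pid, "excluded", "secondary_neoplasia", index)
    met = metastasis_onset(diagnoses, fills, procedures, code_lists, phenotype_config)
    if met is not None and met[0] <= index - timedelta(days=config.prior_met_days):
        return ExclusionOutcome(pid, "excluded", "prior_metastasis", index)
    if _coverage(insurance, patient["death_date"]) < config.coverage_threshold:
        return ExclusionOutcome(pid, "excluded", "insured_too_short", index)
    if patient["death_date"] is not None and patient["death_date"] < index:
        return ExclusionOutcome(pid, "excluded", "death_before_diagnosis", index)
    if patient["sex"] == "male":
        return ExclusionOutcome(pid, "excluded", "male_sex", index)
    return ExclusionOutcome(pid, "included", "none", index)


def classify_control(
    patient: pd.Series,
    diagnoses: pd.DataFrame,
    fills: pd.DataFrame,
    procedures: pd.DataFrame,
    insurance: pd.DataFrame,
    code_lists: CodeLists,
    config: SelectionConfig = SelectionConfig(),
    phenotype_config: PhenotypeConfig = PhenotypeConfig(),
) -> ExclusionOutcome:
    """Apply the control cascade; inclusion is finalized by matching."""
    pid = patient["patient_id"]
    if _has_secondary_neoplasia(diagnoses, config):
        return ExclusionOutcome(pid, "excluded", "secondary_neoplasia")
    met = metastasis_onset(diagnoses, fills, procedures, code_lists, phenotype_config)
    if met is not None:
        return ExclusionOutcome(pid, "excluded", "metastasis")
    if len(insurance) == 0 or _coverage(insurance, patient["death_date"]) < config.coverage_threshold:
        return ExclusionOutcome(pid, "excluded", "insured_too_short")
    if patient["sex"] == "male":
        return ExclusionOutcome(pid, "excluded", "male_sex")
    return ExclusionOutcome(pid, "included", "none")


def select_cohort(
    bundle: ClaimsBundle,
    code_lists: CodeLists,
    config: SelectionConfig = SelectionConfig(),
    phenotype_config: PhenotypeConfig = PhenotypeConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every candidate; returns (case_outcomes, control_outcomes).

    Output columns: patient_id, status, reason, index_date.  Outcomes are
    independent of the input row order (sorted by patient_id).
    """
    grouped = {
        name: dict(tuple(df.groupby("patient_id", sort=False)))
        for name, df in (
            ("diagnoses", bundle.diagnoses),
            ("fills", bundle.fills),
            ("procedures", bundle.procedures),
            ("insurance", bundle.insurance),
        )
    }
    empty = {name: getattr(bundle, name).iloc[0:0] for name in grouped}

    def parts(pid: str):
        return tuple(grouped[n].get(pid, empty[n]) for n in ("diagnoses", "fills", "procedures", "insurance"))

    cases, controls = [], []
    patients = bundle.patients.sort_values("patient_id")
    for _, patient in patients.iterrows():
        pid = patient["patient_id"]
        dx, fills, procs, ins = parts(pid)
        if patient["group"] == "case_candidate":
            cases.append(classify_case(patient, dx, fills, procs, ins, code_lists, config, phenotype_config))
        else:
            controls.append(classify_control(patient, dx, fills, procs, ins, code_lists, config, phenotype_config))
    cols = ["patient_id", "status", "reason", "index_date"]
    return (
        pd.DataFrame([dataclasses.asdict(o) for o in cases], columns=cols),
        pd.DataFrame([dataclasses.asdict(o) for o in controls], columns=cols),
    )


def selection_summary(outcomes: pd.DataFrame, reasons: Iterable[str] | None = None) -> pd.DataFrame:
    """Attrition table: one row per exclusion reason plus Included.

    N per row plus percentage of the candidate total (one decimal,
    half-away-from-zero); row Ns sum to the total.  Empty input yields an
    empty table with total 0.
    """
    from .reporting import percent  # local import: reporting depends on us

    total = len(outcomes)
    if reasons is None:
        reasons = CASE_REASONS
    rows = [{"row": "total", "n": total, "pct": 100.0 if total else 0.0}]
    for reason in reasons:
        n = int((outcomes["reason"] == reason).sum()) if total else 0
        rows.append({"row": f"excluded_{reason}", "n": n,
                     "pct": percent(n, total) if total else 0.0})
    n_inc = int((outcomes["status"] == "included").sum()) if total else 0
    rows.append({"row": "included", "n": n_inc, "pct": percent(n_inc, total) if total else 0.0})
    return pd.DataFrame(rows, columns=["row", "n", "pct"])
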