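"""Claims-based breast-cancer phenotype reconstruction.

German claims carry no tumor pathology, so stage and biology must be
reconstructed from coding behavior:

* **Distant metastasis onset** — direct ICD-10-GM coding of secondary
  neoplasms (C77-C79, excluding axillary C77.3 and unspecified-node C77.9),
  validated inpatient-once or across consecutive outpatient quarters; plus
  four proxy criteria for under-coded disease: sustained chemotherapy
  (>=5 distinct calendar quarters, onset = midpoint of the 5th),
  sustained HER2-antibody therapy (>=7 quarters, midpoint of the 7th),
  metastasis-defining medication (>=2 quarters, midpoint of the 1st), and
  histologic examination of putative malignant lesions (its date).
  The earliest candidate across all criteria wins.
* **Stage** — A: no axillary involvement; B: axillary node code C77.3
  within 6 months of the index diagnosis; C: distant metastasis within
  6 months of the index diagnosis (primary metastatic disease).
* **HR/HER2 subtype** — positive if the corresponding therapy (endocrine,
  resp. HER2-targeted) was filled at least once after the index diagnosis.
  GnRH analogs alone do not establish HR+ (they also protect ovarian
  function during chemotherapy in premenopausal patients).
* **Treatment flags** — breast surgery / radiation via OPS procedure
  codes, systemic (cytotoxic or targeted, not endocrine) therapy via ATC
  fills, all after the index date.

All code sets are configurable; membership is by code-prefix so that
``"L02BG"`` covers every aromatase inhibitor.
"""

from __future__ import annotations

import dataclasses
import warnings
from datetime import date, timedelta
from typing import Iterable

import pandas as pd

from .claims_core import (
    QUARTER_MIDPOINT_OFFSET_DAYS,
    ClaimsBundle,
    ClaimsError,
    ObservationWindow,
    Quarter,
    observation_window,
)

__all__ = [
    "CodeLists",
    "PhenotypeConfig",
    "PhenotypeResult",
    "MET_CRITERIA",
    "SUBTYPES",
    "STAGES",
    "metastasis_onset",
    "assign_stage",
    "assign_subtype",
    "treatment_flags",
    "phenotype_patient",
    "phenotype_cohort",
]

STAGES = ("A", "B", "C")
SUBTYPES = ("HR+/HER2+", "HR+/HER2-", "HR-/HER2+", "HR-/HER2-")
MET_CRITERIA = ("direct_icd", "chemo_5q", "her2_7q", "met_medication_2q", "histology")

#: Distant-metastasis ICD chapter prefixes; C77.3 (axillary) and C77.9
#: (node NOS) are carved out because they do not imply distant disease.
_DISTANT_PREFIXES = ("C77", "C78", "C79")
_DISTANT_EXCLUDED = ("C77.3", "C77.9")


def _matches(code: str, prefixes: frozenset[str] | set[str]) -> bool:
    return any(code.startswith(p) for p in prefixes)


@dataclasses.dataclass(frozen=True)
class CodeLists:
    """Configurable ICD/ATC/OPS code sets used by the phenotyper.

    Drug sets default to the literature-standard breast-cancer therapies:
    endocrine = tamoxifen (L02BA01), fulvestrant (L02BA03) and aromatase
    inhibitors (L02BG); HER2-targeted = trastuzumab (L01XC03), pertuzumab
    (L01XC13), T-DM1 (L01XC14), lapatinib (L01XE07); chemotherapy = the
    L01 antineoplastic chapter minus the HER2-targeted codes.  The
    metastasis-defining-medication and histology-procedure lists have no
    defensible universal default and ship empty (with a warning at use).
    Membership is by prefix.
    """

    endocrine_atc: frozenset[str] = frozenset({"L02BA01", "L02BA03", "L02BG"})
    gnrh_atc: frozenset[str] = frozenset({"L02AE"})
    her2_atc: frozenset[str] = frozenset({"L01XC03", "L01XC13", "L01XC14", "L01XE07"})
    chemo_atc: frozenset[str] = frozenset({"L01"})
    met_defining_atc: frozenset[str] = frozenset()
    histology_ops: frozenset[str] = frozenset()
    surgery_ops: frozenset[str] = frozenset({"5-870", "5-871", "5-872", "5-873", "5-874", "5-875", "5-877"})
    radiation_ops: frozenset[str] = frozenset({"8-52"})

    def __post_init__(self):
        for a, b, name in (
            (self.endocrine_atc, self.gnrh_atc, "endocrine/gnrh"),
            (self.her2_atc, self.met_defining_atc, "her2/met_defining"),
        ):
            for code in a:
                if _matches(code, b) or any(_matches(p, a) for p in b):
                    raise ClaimsError(f"overlapping {name} code lists at {code!r}")

    # drug-class predicates -------------------------------------------------
    def is_endocrine(self, atc: str) -> bool:
        return _matches(atc, self.endocrine_atc) and not _matches(atc, self.gnrh_atc)

    def is_her2(self, atc: str) -> bool:
        return _matches(atc, self.her2_atc)

    def is_chemo(self, atc: str) -> bool:
        # HER2 antibodies sit inside the ATC L01 chapter but are counted
        # separately (their own 7-quarter criterion), never as chemotherapy.
        return _matches(atc, self.chemo_atc) and not self.is_her2(atc)

    def is_met_defining(self, atc: str) -> bool:
        return _matches(atc, self.met_defining_atc)

    def is_distant_met(self, icd: str) -> bool:
        return _matches(icd, _DISTANT_PREFIXES) and not _matches(icd, _DISTANT_EXCLUDED)

    def is_axillary(self, icd: str) -> bool:
        return icd.startswith("C77.3")


@dataclasses.dataclass(frozen=True)
class PhenotypeConfig:
    """Thresholds of the reconstruction rules.

    ``stage_window_days`` is the fixed reading of "6 months";
    ``outpatient_consecutive_quarters`` is the number of consecutive
    outpatient quarters needed to validate a distant-met code ("more than
    two consecutive calendar quarters", read literally as >=3; the common
    German M2Q convention would be 2).
    """

    stage_window_days: int = 183
    outpatient_consecutive_quarters: int = 3
    chemo_quarters: int = 5
    her2_quarters: int = 7
    met_medication_quarters: int = 2
    midpoint_offset_days: int = QUARTER_MIDPOINT_OFFSET_DAYS


@dataclasses.dataclass(frozen=True)
class PhenotypeResult:
    patient_id: str
    index_date: date
    stage: str
    subtype: str
    met_onset: date | None
    met_criterion: str  # one of MET_CRITERIA or "none"
    surgery: bool
    radiation: bool
    systemic_therapy: bool


# ---------------------------------------------------------------------------
# Metastasis onset
# ---------------------------------------------------------------------------


def _distinct_fill_quarters(dates: Iterable[date]) -> list[Quarter]:
    return sorted({quarter_of_date(d) for d in dates})


def quarter_of_date(d: date) -> Quarter:
    return Quarter(d.year, (d.month + 2) // 3)


def _consecutive_run_starts(quarters: list[Quarter], run_len: int) -> list[Quarter]:
    """First quarters of maximal consecutive runs of length >= run_len."""
    if not quarters:
        return []
    starts = []
    run_start, prev, length = quarters[0], quarters[0], 1
    for q in quarters[1:]:
        if q == prev.successor():
            length += 1
        else:
            if length >= run_len:
                starts.append(run_start)
            run_start, length = q, 1
        prev = q
    if length >= run_len:
        starts.append(run_start)
    return starts


def metastasis_onset(
    diagnoses: pd.DataFrame,
    fills: pd.DataFrame,
    procedures: pd.DataFrame,
    code_lists: CodeLists,
    config: PhenotypeConfig = PhenotypeConfig(),
) -> tuple[date, str] | None:
    """First onset of distant metastatic disease for one patient.

    Collects candidate (date, criterion) pairs from direct coding and the
    four proxy criteria and returns the earliest; ties resolve in the
    fixed order of :data:`MET_CRITERIA`.  Returns None if nothing fires.
    """
    offset = config.midpoint_offset_days
    candidates: list[tuple[date, int, str]] = []

    def add(d: date, criterion: str):
        candidates.append((d, MET_CRITERIA.index(criterion), criterion))

    # (a) direct ICD coding: inpatient once, or a consecutive outpatient run
    outpatient_quarters = set()
    for _, row in diagnoses.iterrows():
        if not code_lists.is_distant_met(str(row["icd_code"])):
            continue
        if row["setting"] == "inpatient":
            add(row["date"], "direct_icd")
        else:
            outpatient_quarters.add(Quarter(int(row["quarter_year"]), int(row["quarter_index"])))
    for start in _consecutive_run_starts(
        sorted(outpatient_quarters), config.outpatient_consecutive_quarters
    ):
        add(start.midpoint(offset), "direct_icd")

    # (b)-(d) sustained-therapy proxies on distinct fill quarters
    if len(code_lists.met_defining_atc) == 0 and len(fills):
        warnings.warn(
            "met_defining_atc code list is empty; the metastasis-defining-"
            "medication criterion cannot fire",
            stacklevel=2,
        )
    for predicate, n_quarters, onset_rank, criterion in (
        (code_lists.is_chemo, config.chemo_quarters, config.chemo_quarters, "chemo_5q"),
        (code_lists.is_her2, config.her2_quarters, config.her2_quarters, "her2_7q"),
        (code_lists.is_met_defining, config.met_medication_quarters, 1, "met_medication_2q"),
    ):
        dates = [row["fill_date"] for _, row in fills.iterrows() if predicate(str(row["atc_code"]))]
        quarters = _distinct_fill_quarters(dates)
        if len(quarters) >= n_quarters:
            add(quarters[onset_rank - 1].midpoint(offset), criterion)

    # (e) histologic examination of putative malignant lesions
    for _, row in procedures.iterrows():
        if _matches(str(row["ops_code"]), code_lists.histology_ops):
            add(row["date"], "histology")

    if not candidates:
        return None
    d, _, criterion = min(candidates)
    return d, criterion


# ---------------------------------------------------------------------------
# Stage, subtype, treatment
# ---------------------------------------------------------------------------


def assign_stage(
    met_onset: date | None,
    axillary_dates: Iterable[date],
    index_date: date,
    config: PhenotypeConfig = PhenotypeConfig(),
) -> str:
    """Stage A/B/C from metastasis onset and axillary-node coding.

    Stage C requires distant metastasis within the 6-month window around
    the index diagnosis (two-sided: onsets up to 183 days *before* the
    index are still primary metastatic, since earlier onsets were already
    excluded by cohort selection).  Stage B requires axillary C77.3 within
    183 days after the index; otherwise stage A.
    """
    w = timedelta(days=config.stage_window_days)
    if met_onset is not None and index_date - w < met_onset <= index_date + w:
        return "C"
    if any(index_date <= d <= index_date + w for d in axillary_dates):
        return "B"
    return "A"


def assign_subtype(
    fills: pd.DataFrame,
    index_date: date,
    window: ObservationWindow,
    code_lists: CodeLists,
) -> str:
    """HR/HER2 subtype from post-index prescription fills.

    A patient is HR+ (resp. HER2+) iff at least one endocrine (resp.
    HER2-targeted) prescription was filled strictly after the index
    diagnosis and within the observation window.  GnRH analogs never
    count toward HR+.
    """
    hr = her2 = False
    for _, row in fills.iterrows():
        d = row["fill_date"]
        if not index_date < d <= window.end:
            continue
        atc = str(row["atc_code"])
        hr = hr or code_lists.is_endocrine(atc)
        her2 = her2 or code_lists.is_her2(atc)
    return f"HR{'+' if hr else '-'}/HER2{'+' if her2 else '-'}"


def treatment_flags(
    procedures: pd.DataFrame,
    fills: pd.DataFrame,
    index_date: date,
    window: ObservationWindow,
    code_lists: CodeLists,
) -> tuple[bool, bool, bool]:
    """(surgery, radiation, systemic_therapy) flags, all post-index.

    Systemic therapy covers cytotoxic, HER2-targeted and metastasis-
    defining drugs; endocrine therapy is tracked via the subtype instead.
    """
    surgery = radiation = systemic = False
    for _, row in procedures.iterrows():
        d = row["date"]
        if not index_date < d <= window.end:
            continue
        ops = str(row["ops_code"])
        surgery = surgery or _matches(ops, code_lists.surgery_ops)
        radiation = radiation or _matches(ops, code_lists.radiation_ops)
    for _, row in fills.iterrows():
        d = row["fill_date"]
        if not index_date < d <= window.end:
            continue
        atc = str(row["atc_code"])
        if code_lists.is_chemo(atc) or code_lists.is_her2(atc) or code_lists.is_met_defining(atc):
            systemic = True
            break
    return surgery, radiation, systemic


# ---------------------------------------------------------------------------
# Per-patient and cohort drivers
# ---------------------------------------------------------------------------


def _axillary_dates(diagnoses: pd.DataFrame, code_lists: CodeLists, offset: int) -> list[date]:
    out = []
    for _, row in diagnoses.iterrows():
        if not code_lists.is_axillary(str(row["icd_code"])):
            continue
        if row["setting"] == "inpatient":
            out.append(row["date"])
        else:
            out.append(Quarter(int(row["quarter_year"]), int(row["quarter_index"])).midpoint(offset))
    return out


def phenotype_patient(
    bundle: ClaimsBundle,
    patient_id: str,
    index_date: date,
    code_lists: CodeLists,
    config: PhenotypeConfig = PhenotypeConfig(),
) -> PhenotypeResult:
    """Full phenotype reconstruction for one included case."""
    pat = bundle.patients.loc[bundle.patients["patient_id"] == patient_id]
    if pat.empty:
        raise ClaimsError(f"unknown patient {patient_id!r}")
    window = observation_window(pat.iloc[0]["death_date"])

    dx = bundle.diagnoses.loc[bundle.diagnoses["patient_id"] == patient_id]
    fills = bundle.fills.loc[bundle.fills["patient_id"] == patient_id]
    procs = bundle.procedures.loc[bundle.procedures["patient_id"] == patient_id]

    met = metastasis_onset(dx, fills, procs, code_lists, config)
    met_onset_date, criterion = met if met is not None else (None, "none")
    stage = assign_stage(
        met_onset_date,
        _axillary_dates(dx, code_lists, config.midpoint_offset_days),
        index_date,
        config,
    )
    subtype = assign_subtype(fills, index_date, window, code_lists)
    surgery, radiation, systemic = treatment_flags(procs, fills, index_date, window, code_lists)
    return PhenotypeResult(
        patient_id=patient_id,
        index_date=index_date,
        stage=stage,
        subtype=subtype,
        met_onset=met_onset_date,
        met_criterion=criterion,
        surgery=surgery,
        radiation=radiation,
        systemic_therapy=systemic,
    )


def phenotype_cohort(
    bundle: ClaimsBundle,
    index_dates: dict[str, date],
    code_lists: CodeLists,
    config: PhenotypeConfig = PhenotypeConfig(),
) -> pd.DataFrame:
    """Phenotype every included case; returns one row per patient.

    ``index_dates`` maps patient_id -> index diagnosis date (from cohort
    selection).  Output columns: patient_id, index_date, stage, subtype,
    met_onset, met_criterion, surgery, radiation, systemic_therapy.
    """
    # group every event table once; per-patient filtering would rescan the
    # full bundle for each case
    grouped = {
        name: dict(tuple(df.groupby("patient_id", sort=False)))
        for name, df in (
            ("diagnoses", bundle.diagnoses),
            ("fills", bundle.fills),
            ("procedures", bundle.procedures),
        )
    }
    empty = {name: getattr(bundle, name).iloc[0:0] for name in grouped}
    death_dates = dict(zip(bundle.patients["patient_id"], bundle.patients["death_date"]))

    rows = []
    for pid, idx in sorted(index_dates.items()):
        if pid not in death_dates:
            raise ClaimsError(f"unknown patient {pid!r}")
        window = observation_window(death_dates[pid])
        dx = grouped["diagnoses"].get(pid, empty["diagnoses"])
        fills = grouped["fills"].get(pid, empty["fills"])
        procs = grouped["procedures"].get(pid, empty["procedures"])
        met = metastasis_onset(dx, fills, procs, code_lists, config)
        met_onset_date, criterion = met if met is not None else (None, "none")
        stage = assign_stage(
            met_onset_date,
            _axillary_dates(dx, code_lists, config.midpoint_offset_days),
            idx,
            config,
        )
        subtype = assign_subtype(fills, idx, window, code_lists)
        surgery, radiation, systemic = treatment_flags(procs, fills, idx, window, code_lists)
        rows.append(
            dataclasses.asdict(
                PhenotypeResult(pid, idx, stage, subtype, met_onset_date,
                                criterion, surgery, radiation, systemic)
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "index_date", "stage", "subtype", "met_onset",
            "met_criterion", "surgery", "radiation", "systemic_therapy",
        ],
    )
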