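"""Synthetic statutory-claims generator with known ground truth.

The real claims snapshot behind this disease model is not public, so this
module fabricates a population with the same observable structure — a
breast-cancer candidate group and a control candidate group, quarter-
resolved outpatient coding, ATC prescription fills, OPS procedures,
insurance periods and deaths — while recording the generating truth
(diagnosis date, stage, subtype, metastasis onset, death) for every
patient.  Every downstream stage (selection, phenotyping, matching,
survival) can then be tested as a parameter-recovery problem.

Two-phase design:

* :func:`generate_cohort` emits a *clean* bundle whose coding is fully
  consistent with the truth: the index diagnosis is coded inpatient on
  the true date, axillary involvement (stage B) as C77.3 within 6 months,
  distant metastasis (stage C, and late recurrences) as direct inpatient
  C78 coding, subtypes as post-index endocrine / HER2-antibody fills, and
  survival from per-(stage, subtype) exponential hazards.
* :func:`inject_coding_gaps` then degrades coding the way real claims do:
  suppressing direct metastasis codes in favor of one of the four proxy
  signals (sustained chemo, sustained HER2 antibodies, metastasis-
  defining medication, histology), demoting the C50 coding to outpatient-
  only, injecting second primaries, shortening insurance, and planting
  the analogous defects in controls.

Injected proxies are constructed so that the onset implied by the
quarter-midpoint convention equals the truth date's quarter midpoint,
i.e. the dating error is at most 46 days.

Default marginals are the study conditions: age bands
(0.160, 0.214, 0.227, 0.227, 0.171), subtypes
(HR+/HER2+ 0.069, HR+/HER2- 0.709, HR-/HER2+ 0.029, HR-/HER2- 0.192)
and stages (A 0.678, B 0.170, C 0.152).
"""

from __future__ import annotations

import dataclasses
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .claims_core import (
    STUDY_END,
    STUDY_START,
    ClaimsBundle,
    ClaimsError,
    Quarter,
    quarter_of,
)
from .phenotyping import SUBTYPES, CodeLists

__all__ = [
    "AGE_BANDS",
    "SYNTHETIC_CODE_LISTS",
    "GapProbs",
    "AdherenceProbs",
    "ControlDefectProbs",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "inject_coding_gaps",
    "write_ground_truth",
    "load_ground_truth",
]

#: (label, youngest age, oldest age) at diagnosis
AGE_BANDS = (
    ("<50", 30, 49),
    ("50s", 50, 59),
    ("60s", 60, 69),
    ("70s", 70, 79),
    (">=80", 80, 94),
)

#: Deaths in the source data were reported until this date.
DEATH_REPORTING_END = date(2022, 5, 31)

#: Code lists matching what this generator emits: standard breast-cancer
#: ATC/OPS defaults plus V10 (therapeutic radiopharmaceuticals, e.g.
#: radium-223 for bone metastases) as the metastasis-defining medication
#: class and OPS 1-56 (deep-organ biopsies) as histology procedures.
SYNTHETIC_CODE_LISTS = CodeLists(
    met_defining_atc=frozenset({"V10"}),
    histology_ops=frozenset({"1-56"}),
)

_ENDOCRINE_ATC = ("L02BA01", "L02BG04", "L02BG06")
_HER2_ATC = "L01XC03"
_GNRH_ATC = "L02AE03"
_CHEMO_ATC = ("L01CA04", "L01BC02", "L01CD01")
_MET_DEFINING_ATC = "V10XX03"
_HISTOLOGY_OPS = "1-563"
_SURGERY_OPS = "5-870"
_RADIATION_OPS = "8-52"
_SECOND_PRIMARY_ICD = "C34.1"
_DISTANT_MET_ICD = "C78.0"
_AXILLARY_ICD = "C77.3"

_INDEX_WINDOW = (date(2010, 7, 1), date(2019, 12, 31))


def _check_probs(name: str, probs, n: int) -> np.ndarray:
    v = np.asarray(probs, dtype=float)
    if v.shape != (n,) or np.any(v < 0) or abs(v.sum() - 1.0) > 5e-3:
        raise ClaimsError(f"{name} must be {n} non-negative probabilities summing to 1")
    return v / v.sum()


@dataclasses.dataclass(frozen=True)
class GapProbs:
    """Coding-defect probabilities for case candidates.

    ``metastasis``: suppress a stage-C case's direct C77-C79 coding and
    replace it with exactly one proxy signal.  ``outpatient_only_c50``,
    ``secondary_neoplasia`` and ``short_insurance`` plant the defects the
    exclusion cascade is designed to catch, at the attrition rates seen
    in the source population (51.6%, 9.9%, 0.7%); the direct-coding gap
    rate is not reported and defaults to 0.25.
    """

    metastasis: float = 0.25
    outpatient_only_c50: float = 0.516
    secondary_neoplasia: float = 0.099
    short_insurance: float = 0.007


@dataclasses.dataclass(frozen=True)
class AdherenceProbs:
    """Probability that an HR+ (resp. HER2+) truth patient fills the
    corresponding therapy at least once.  Truth subtypes are calibrated
    to the prescription-defined prevalences, so full adherence is the
    self-consistent default."""

    hr: float = 1.0
    her2: float = 1.0


@dataclasses.dataclass(frozen=True)
class ControlDefectProbs:
    """Control-side defects at the source population's attrition rates
    (secondary neoplasia 11.6%, metastasis coding 3.2%, short insurance
    2.7%)."""

    secondary_neoplasia: float = 0.116
    metastasis: float = 0.032
    short_insurance: float = 0.027


def _default_death_hazards() -> dict[tuple[str, str], float]:
    # per-year exponential death rates honoring the observed ordering:
    # stage A best / C worst, triple-negative worst within every stage
    base = {"A": 0.035, "B": 0.06, "C": 0.30}
    mult = {"HR+/HER2+": 0.8, "HR+/HER2-": 1.0, "HR-/HER2+": 1.1, "HR-/HER2-": 1.6}
    return {(s, t): base[s] * mult[t] for s in base for t in mult}


def _default_met_hazards() -> dict[str, float]:
    # per-year rate of late (post-window) distant recurrence
    return {"A": 0.02, "B": 0.05}


@dataclasses.dataclass(frozen=True)
class SyntheticConfig:
    """Full generative description of one synthetic population."""

    n_cases: int
    n_control_candidates: int
    seed: int
    age_band_probs: tuple[float, ...] = (0.160, 0.214, 0.227, 0.227, 0.171)
    subtype_probs: tuple[float, ...] = (0.069, 0.709, 0.029, 0.192)
    stage_probs: tuple[float, ...] = (0.678, 0.170, 0.152)
    death_hazards: dict = dataclasses.field(default_factory=_default_death_hazards)
    met_hazards: dict = dataclasses.field(default_factory=_default_met_hazards)
    control_death_hazard: float = 0.036
    coding_gap_probs: GapProbs = GapProbs()
    adherence_probs: AdherenceProbs = AdherenceProbs()
    control_defect_probs: ControlDefectProbs = ControlDefectProbs()
    case_male_prob: float = 0.017
    control_male_prob: float = 0.012

    def __post_init__(self):
        if self.n_cases < 0 or self.n_control_candidates < 0:
            raise ClaimsError("population sizes must be non-negative")
        if self.n_control_candidates < 2 * self.n_cases:
            raise ClaimsError(
                "need at least two control candidates per case for 1:2 matching"
            )
        _check_probs("age_band_probs", self.age_band_probs, len(AGE_BANDS))
        _check_probs("subtype_probs", self.subtype_probs, len(SUBTYPES))
        _check_probs("stage_probs", self.stage_probs, 3)
        for key, rate in {**{str(k): v for k, v in self.death_hazards.items()},
                          **{str(k): v for k, v in self.met_hazards.items()},
                          "control": self.control_death_hazard}.items():
            if rate <= 0:
                raise ClaimsError(f"hazard {key} must be positive")

    # -- structured-text round trip ----------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["death_hazards"] = {f"{s}|{t}": v for (s, t), v in self.death_hazards.items()}
        d["age_band_probs"] = list(self.age_band_probs)
        d["subtype_probs"] = list(self.subtype_probs)
        d["stage_probs"] = list(self.stage_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "seed" not in d:
            raise ClaimsError("synthetic config requires an explicit seed")
        if "death_hazards" in d:
            d["death_hazards"] = {
                tuple(k.split("|")): v for k, v in d["death_hazards"].items()
            }
        for key, typ in (("coding_gap_probs", GapProbs),
                         ("adherence_probs", AdherenceProbs),
                         ("control_defect_probs", ControlDefectProbs)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        for key in ("age_band_probs", "subtype_probs", "stage_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclasses.dataclass
class GroundTruth:
    """Generating truth: one row per case and per control candidate."""

    cases: pd.DataFrame
    controls: pd.DataFrame


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _uniform_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    return lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def generate_cohort(cfg: SyntheticConfig) -> tuple[ClaimsBundle, GroundTruth]:
    """Clean, truth-consistent claims bundle plus its ground truth.

    Deterministic given the config (the seed is part of it).  Controls
    carry no C50 coding; every emitted event is consistent with the truth
    row of its patient.
    """
    rng = np.random.default_rng(cfg.seed)
    patients, insurance, diagnoses, fills, procedures = [], [], [], [], []
    truth_cases, truth_controls = [], []

    age_probs = _check_probs("age_band_probs", cfg.age_band_probs, len(AGE_BANDS))
    subtype_probs = _check_probs("subtype_probs", cfg.subtype_probs, len(SUBTYPES))
    stage_probs = _check_probs("stage_probs", cfg.stage_probs, 3)

    n = cfg.n_cases
    bands = rng.choice(len(AGE_BANDS), size=n, p=age_probs)
    stages = rng.choice(list("ABC"), size=n, p=stage_probs)
    subtypes = rng.choice(SUBTYPES, size=n, p=subtype_probs)
    males = rng.random(n) < cfg.case_male_prob
    index_offsets = rng.integers(0, (_INDEX_WINDOW[1] - _INDEX_WINDOW[0]).days + 1, size=n)

    def add_dx(pid, icd, d):
        diagnoses.append({"patient_id": pid, "icd_code": icd, "setting": "inpatient",
                          "date": d, "quarter_year": None, "quarter_index": None})

    def add_fill(pid, atc, d):
        fills.append({"patient_id": pid, "atc_code": atc, "fill_date": d})

    def fill_schedule(pid, atc, first, step, count, horizon):
        d = first
        for _ in range(count):
            if d > horizon:
                break
            add_fill(pid, atc, d)
            d = d + timedelta(days=step)

    for i in range(n):
        pid = f"P{i:06d}"
        dx = _INDEX_WINDOW[0] + timedelta(days=int(index_offsets[i]))
        lo, hi = AGE_BANDS[bands[i]][1], AGE_BANDS[bands[i]][2]
        birth_year = dx.year - int(rng.integers(lo, hi + 1))
        stage, subtype = str(stages[i]), str(subtypes[i])
        sex = "male" if males[i] else "female"

        # survival from the per-(stage, subtype) exponential hazard
        t_death_years = rng.exponential(1.0 / cfg.death_hazards[(stage, subtype)])
        death = dx + timedelta(days=max(1, int(round(t_death_years * 365.25))))
        death_recorded = death if death <= DEATH_REPORTING_END else None
        alive_until = min(death, STUDY_END)

        # metastasis truth
        met: date | None = None
        if stage == "C":
            met = dx + timedelta(days=int(rng.integers(-30, 151)))
            met = min(met, death)
        elif stage in cfg.met_hazards:
            t_met = rng.exponential(1.0 / cfg.met_hazards[stage])
            cand = dx + timedelta(days=184 + int(t_met * 365.25))
            if cand <= alive_until:
                met = cand

        patients.append({"patient_id": pid, "sex": sex, "birth_year": birth_year,
                         "death_date": death_recorded, "group": "case_candidate"})
        insurance.append({"patient_id": pid, "start_date": STUDY_START, "end_date": STUDY_END})
        add_dx(pid, "C50.4", dx)
        if stage == "B":
            upper = min(183, (alive_until - dx).days)
            add_dx(pid, _AXILLARY_ICD, dx + timedelta(days=int(rng.integers(0, max(upper, 0) + 1))))
        if met is not None:
            add_dx(pid, _DISTANT_MET_ICD, met)

        # therapy fills consistent with the truth subtype
        hr_truth = subtype.startswith("HR+")
        her2_truth = "HER2+" in subtype
        hr_adherent = hr_truth and rng.random() < cfg.adherence_probs.hr
        her2_adherent = her2_truth and rng.random() < cfg.adherence_probs.her2
        if hr_adherent:
            atc = str(rng.choice(_ENDOCRINE_ATC))
            fill_schedule(pid, atc, min(dx + timedelta(days=30), alive_until), 91,
                          int(rng.integers(4, 9)), alive_until)
        if her2_adherent:
            # at most 6 distinct quarters: sustained antibody therapy is a
            # metastasis proxy from the 7th quarter on
            fill_schedule(pid, _HER2_ATC, min(dx + timedelta(days=21), alive_until), 91,
                          int(rng.integers(3, 7)), alive_until)
        if birth_year > dx.year - 50 and rng.random() < 0.3:
            fill_schedule(pid, _GNRH_ATC, min(dx + timedelta(days=35), alive_until), 91, 2, alive_until)
        chemo_prob = {"A": 0.2, "B": 0.5, "C": 0.8}[stage]
        if rng.random() < chemo_prob:
            atc = str(rng.choice(_CHEMO_ATC))
            # at most 4 distinct quarters (5 would trip the chemo proxy)
            fill_schedule(pid, atc, min(dx + timedelta(days=40), alive_until), 91,
                          int(rng.integers(2, 5)), alive_until)

        surgery_prob = {"A": 0.9, "B": 0.9, "C": 0.35}[stage]
        if rng.random() < surgery_prob and dx + timedelta(days=14) <= alive_until:
            procedures.append({"patient_id": pid, "ops_code": _SURGERY_OPS,
                               "date": dx + timedelta(days=14)})
        radiation_prob = {"A": 0.6, "B": 0.7, "C": 0.3}[stage]
        if rng.random() < radiation_prob and dx + timedelta(days=60) <= alive_until:
            procedures.append({"patient_id": pid, "ops_code": _RADIATION_OPS + "0",
                               "date": dx + timedelta(days=60)})

        truth_cases.append({
            "patient_id": pid, "sex": sex, "birth_year": birth_year,
            "diagnosis_date": dx, "stage": stage, "subtype": subtype,
            "met_date": met, "death_date": death_recorded,
            "hr_adherent": bool(hr_adherent), "her2_adherent": bool(her2_adherent),
            "gap_metastasis": "", "gap_outpatient_c50": False,
            "gap_secondary_neoplasia": False, "gap_short_insurance": False,
        })

    # controls: same age structure relative to a pseudo-index date
    m = cfg.n_control_candidates
    c_bands = rng.choice(len(AGE_BANDS), size=m, p=age_probs)
    c_males = rng.random(m) < cfg.control_male_prob
    c_pseudo = rng.integers(0, (_INDEX_WINDOW[1] - _INDEX_WINDOW[0]).days + 1, size=m)
    c_death_years = rng.exponential(1.0 / cfg.control_death_hazard, size=m)
    for j in range(m):
        pid = f"K{j:06d}"
        pseudo = _INDEX_WINDOW[0] + timedelta(days=int(c_pseudo[j]))
        lo, hi = AGE_BANDS[c_bands[j]][1], AGE_BANDS[c_bands[j]][2]
        birth_year = pseudo.year - int(rng.integers(lo, hi + 1))
        death = STUDY_START + timedelta(days=max(1, int(round(c_death_years[j] * 365.25))))
        death_recorded = death if death <= DEATH_REPORTING_END else None
        patients.append({"patient_id": pid, "sex": "male" if c_males[j] else "female",
                         "birth_year": birth_year, "death_date": death_recorded,
                         "group": "control_candidate"})
        insurance.append({"patient_id": pid, "start_date": STUDY_START, "end_date": STUDY_END})
        truth_controls.append({
            "patient_id": pid, "sex": "male" if c_males[j] else "female",
            "birth_year": birth_year, "death_date": death_recorded,
            "defect_secondary_neoplasia": False, "defect_metastasis": False,
            "defect_short_insurance": False,
        })

    bundle = ClaimsBundle(
        patients=pd.DataFrame(patients, columns=["patient_id", "sex", "birth_year", "death_date", "group"]),
        insurance=pd.DataFrame(insurance, columns=["patient_id", "start_date", "end_date"]),
        diagnoses=pd.DataFrame(diagnoses, columns=["patient_id", "icd_code", "setting", "date", "quarter_year", "quarter_index"]),
        fills=pd.DataFrame(fills, columns=["patient_id", "atc_code", "fill_date"]),
        procedures=pd.DataFrame(procedures, columns=["patient_id", "ops_code", "date"]),
    )
    bundle.diagnoses["quarter_year"] = bundle.diagnoses["quarter_year"].astype("Int64")
    bundle.diagnoses["quarter_index"] = bundle.diagnoses["quarter_index"].astype("Int64")
    truth = GroundTruth(
        cases=pd.DataFrame(truth_cases),
        controls=pd.DataFrame(truth_controls),
    )
    if m == 0:
        truth.controls = pd.DataFrame(
            columns=["patient_id", "sex", "birth_year", "death_date",
                     "defect_secondary_neoplasia", "defect_metastasis", "defect_short_insurance"]
        )
    return bundle, truth


# ---------------------------------------------------------------------------
# Coding-gap injection
# ---------------------------------------------------------------------------


def _proxy_for(subtype: str, met_q: Quarter, rng: np.random.Generator) -> str:
    """Choose the replacement proxy for a suppressed direct coding.

    HER2+ patients get the HER2-antibody criterion (antibody therapy
    implies HER2+); others draw among chemo, metastasis-defining
    medication and histology.  Quarter-run proxies need enough study-era
    quarters before the onset quarter; near the era start the date-exact
    histology proxy is used instead.
    """
    first_q = Quarter(2010, 1)

    def quarters_before(q: Quarter, k: int) -> bool:
        back = q
        for _ in range(k):
            back = back.predecessor()
        return back >= first_q

    if "HER2+" in subtype and quarters_before(met_q, 6):
        return "her2_7q"
    choice = str(rng.choice(["chemo_5q", "met_medication_2q", "histology"]))
    if choice == "chemo_5q" and not quarters_before(met_q, 4):
        return "histology"
    return choice


def _run_of_quarters(end_q: Quarter, count: int) -> list[Quarter]:
    qs = [end_q]
    for _ in range(count - 1):
        qs.append(qs[-1].predecessor())
    return list(reversed(qs))


def inject_coding_gaps(
    bundle: ClaimsBundle, truth: GroundTruth, cfg: SyntheticConfig
) -> ClaimsBundle:
    """Degrade a clean bundle with realistic coding defects.

    Returns a new bundle; ``truth`` gap/defect flag columns are updated
    in place.  Deterministic given the config seed.  With all gap
    probabilities zero the bundle is returned unchanged.
    """
    g = cfg.coding_gap_probs
    cd = cfg.control_defect_probs
    if (g.metastasis == g.outpatient_only_c50 == g.secondary_neoplasia
            == g.short_insurance == 0.0
            and cd.secondary_neoplasia == cd.metastasis == cd.short_insurance == 0.0):
        return bundle

    rng = np.random.default_rng((cfg.seed + 1) % 2**31)
    diagnoses = bundle.diagnoses.copy()
    fills = bundle.fills.copy()
    procedures = bundle.procedures.copy()
    insurance = bundle.insurance.copy()
    new_dx, new_fills, new_procs = [], [], []

    drop_dx = np.zeros(len(diagnoses), dtype=bool)
    drop_fills = np.zeros(len(fills), dtype=bool)
    dx_by_pid = diagnoses.groupby("patient_id", sort=False).indices
    fills_by_pid = fills.groupby("patient_id", sort=False).indices
    short_insurance: list[tuple[str, date | None]] = []  # (pid, recorded death)

    def suppress(pid, frame_indices, drop_mask, predicate, frame):
        for k in frame_indices.get(pid, []):
            if predicate(frame.iloc[k]):
                drop_mask[k] = True

    tc = truth.cases
    for i in tc.index:
        row = tc.loc[i]
        pid = row["patient_id"]
        # (1) suppress direct metastasis coding, plant one proxy (stage C)
        if row["stage"] == "C" and row["met_date"] is not None and rng.random() < g.metastasis:
            met = row["met_date"]
            met_q = quarter_of(met)
            criterion = _proxy_for(row["subtype"], met_q, rng)
            suppress(pid, dx_by_pid, drop_dx,
                     lambda r: SYNTHETIC_CODE_LISTS.is_distant_met(str(r["icd_code"])),
                     diagnoses)
            if criterion == "chemo_5q":
                suppress(pid, fills_by_pid, drop_fills,
                         lambda r: SYNTHETIC_CODE_LISTS.is_chemo(str(r["atc_code"])), fills)
                for q in _run_of_quarters(met_q, 5):
                    new_fills.append({"patient_id": pid, "atc_code": _CHEMO_ATC[0],
                                      "fill_date": min(q.midpoint(), met)})
            elif criterion == "her2_7q":
                for q in _run_of_quarters(met_q, 7):
                    new_fills.append({"patient_id": pid, "atc_code": _HER2_ATC,
                                      "fill_date": min(q.midpoint(), met)})
            elif criterion == "met_medication_2q":
                for q in (met_q, met_q.successor()):
                    d = min(max(q.first_day, met), STUDY_END)
                    new_fills.append({"patient_id": pid, "atc_code": _MET_DEFINING_ATC,
                                      "fill_date": d})
            else:  # histology: date-exact
                new_procs.append({"patient_id": pid, "ops_code": _HISTOLOGY_OPS, "date": met})
            tc.loc[i, "gap_metastasis"] = criterion
        # (2) demote C50 to outpatient-only
        if rng.random() < g.outpatient_only_c50:
            dx_date = row["diagnosis_date"]
            suppress(pid, dx_by_pid, drop_dx,
                     lambda r: str(r["icd_code"]).startswith("C50"), diagnoses)
            q = quarter_of(dx_date)
            new_dx.append({"patient_id": pid, "icd_code": "C50.4", "setting": "outpatient",
                           "date": None, "quarter_year": q.year, "quarter_index": q.index})
            tc.loc[i, "gap_outpatient_c50"] = True
        # (3) second primary
        if rng.random() < g.secondary_neoplasia:
            d = _uniform_date(rng, STUDY_START, STUDY_END)
            new_dx.append({"patient_id": pid, "icd_code": _SECOND_PRIMARY_ICD,
                           "setting": "inpatient", "date": d,
                           "quarter_year": None, "quarter_index": None})
            tc.loc[i, "gap_secondary_neoplasia"] = True
        # (4) short insurance
        if rng.random() < g.short_insurance:
            short_insurance.append((pid, row["death_date"]))
            tc.loc[i, "gap_short_insurance"] = True

    tr = truth.controls
    for i in tr.index:
        row = tr.loc[i]
        pid = row["patient_id"]
        horizon = row["death_date"] if row["death_date"] is not None else STUDY_END
        horizon = min(horizon, STUDY_END)
        if rng.random() < cd.secondary_neoplasia:
            new_dx.append({"patient_id": pid, "icd_code": _SECOND_PRIMARY_ICD,
                           "setting": "inpatient", "date": _uniform_date(rng, STUDY_START, horizon),
                           "quarter_year": None, "quarter_index": None})
            tr.loc[i, "defect_secondary_neoplasia"] = True
        if rng.random() < cd.metastasis:
            new_dx.append({"patient_id": pid, "icd_code": _DISTANT_MET_ICD,
                           "setting": "inpatient", "date": _uniform_date(rng, STUDY_START, horizon),
                           "quarter_year": None, "quarter_index": None})
            tr.loc[i, "defect_metastasis"] = True
        if rng.random() < cd.short_insurance:
            short_insurance.append((pid, row["death_date"]))
            tr.loc[i, "defect_short_insurance"] = True

    if short_insurance:
        keep = ~insurance["patient_id"].isin([p for p, _ in short_insurance])
        short_rows = []
        for pid, death in short_insurance:
            # 30% of the patient's own observation window, safely under
            # the 40% inclusion threshold
            end = min(death, STUDY_END) if death is not None else STUDY_END
            window_days = (end - STUDY_START).days + 1
            short_rows.append({
                "patient_id": pid, "start_date": STUDY_START,
                "end_date": STUDY_START + timedelta(days=max(0, int(0.30 * window_days) - 1)),
            })
        insurance = pd.concat([insurance.loc[keep], pd.DataFrame(short_rows)], ignore_index=True)

    if new_dx:
        add = pd.DataFrame(new_dx, columns=diagnoses.columns)
        for col in ("quarter_year", "quarter_index"):
            add[col] = add[col].astype("Int64")
            diagnoses[col] = diagnoses[col].astype("Int64")
        diagnoses = pd.concat([diagnoses.loc[~drop_dx], add], ignore_index=True)
    else:
        diagnoses = diagnoses.loc[~drop_dx].reset_index(drop=True)
    fills = pd.concat(
        [fills.loc[~drop_fills]] + ([pd.DataFrame(new_fills)] if new_fills else []),
        ignore_index=True,
    )
    procedures = pd.concat(
        [procedures] + ([pd.DataFrame(new_procs)] if new_procs else []),
        ignore_index=True,
    )
    return ClaimsBundle(
        patients=bundle.patients.copy(),
        insurance=insurance,
        diagnoses=diagnoses,
        fills=fills,
        procedures=procedures,
    )


# ---------------------------------------------------------------------------
# Ground-truth IO
# ---------------------------------------------------------------------------

_TRUTH_DATE_COLS = ("diagnosis_date", "met_date", "death_date")


def write_ground_truth(truth: GroundTruth, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in (("ground_truth_cases", truth.cases), ("ground_truth_controls", truth.controls)):
        out = df.copy()
        for col in _TRUTH_DATE_COLS:
            if col in out.columns:
                out[col] = out[col].map(lambda d: "" if d is None or pd.isna(d) else d.isoformat())
        out.to_csv(directory / f"{name}.csv", index=False)


def load_ground_truth(directory: str | Path) -> GroundTruth:
    directory = Path(directory)
    frames = {}
    for name in ("ground_truth_cases", "ground_truth_controls"):
        df = pd.read_csv(directory / f"{name}.csv", dtype=str, keep_default_na=False)
        for col in _TRUTH_DATE_COLS:
            if col in df.columns:
                df[col] = df[col].map(lambda v: None if v == "" else date.fromisoformat(v))
        for col in df.columns:
            if col.startswith(("gap_", "defect_", "hr_", "her2_")) and col != "gap_metastasis":
                df[col] = df[col] == "True"
        if "birth_year" in df.columns:
            df["birth_year"] = df["birth_year"].astype(int)
        frames[name] = df
    return GroundTruth(cases=frames["ground_truth_cases"], controls=frames["ground_truth_controls"])
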