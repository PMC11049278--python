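"""Shared builders for small hand-constructed claims bundles."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from bcclaims.claims_core import STUDY_END, STUDY_START, ClaimsBundle
from bcclaims.synthetic_claims import SYNTHETIC_CODE_LISTS


def patient(pid, sex="female", birth_year=1950, death=None, group="case_candidate"):
    return {"patient_id": pid, "sex": sex, "birth_year": birth_year,
            "death_date": death, "group": group}


def dx_in(pid, icd, d):
    return {"patient_id": pid, "icd_code": icd, "setting": "inpatient",
            "date": d, "quarter_year": None, "quarter_index": None}


def dx_out(pid, icd, year, quarter):
    return {"patient_id": pid, "icd_code": icd, "setting": "outpatient",
            "date": None, "quarter_year": year, "quarter_index": quarter}


def fill(pid, atc, d):
    return {"patient_id": pid, "atc_code": atc, "fill_date": d}


def proc(pid, ops, d):
    return {"patient_id": pid, "ops_code": ops, "date": d}


def ins(pid, start=STUDY_START, end=STUDY_END):
    return {"patient_id": pid, "start_date": start, "end_date": end}


def make_bundle(patients, diagnoses=(), fills=(), procedures=(), insurance=None):
    """Bundle from row dicts; full-era insurance by default."""
    if insurance is None:
        insurance = [ins(p["patient_id"]) for p in patients]
    dx = pd.DataFrame(list(diagnoses), columns=["patient_id", "icd_code", "setting", "date", "quarter_year", "quarter_index"])
    dx["quarter_year"] = dx["quarter_year"].astype("Int64")
    dx["quarter_index"] = dx["quarter_index"].astype("Int64")
    return ClaimsBundle(
        patients=pd.DataFrame(list(patients), columns=["patient_id", "sex", "birth_year", "death_date", "group"]),
        insurance=pd.DataFrame(list(insurance), columns=["patient_id", "start_date", "end_date"]),
        diagnoses=dx,
        fills=pd.DataFrame(list(fills), columns=["patient_id", "atc_code", "fill_date"]),
        procedures=pd.DataFrame(list(procedures), columns=["patient_id", "ops_code", "date"]),
    )


@pytest.fixture(scope="session")
def code_lists():
    return SYNTHETIC_CODE_LISTS
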