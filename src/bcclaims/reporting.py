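"""Summary tables, curve export and full-pipeline orchestration.

The pipeline runs load/generate -> select -> phenotype -> match ->
survival -> report and writes every intermediate as CSV, with a run log
recording the record counts at each stage (an attrition trail mirroring
the selection summary).  All percentages in emitted tables derive from
their own N columns through :func:`percent`, which rounds half away from
zero to one decimal — the convention of the printed tables this layout
follows (bankers' rounding would differ on ties).
"""

from __future__ import annotations

import dataclasses
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .claims_core import (
    ClaimsBundle,
    ClaimsError,
    load_claims_bundle,
    merge_periods,
    write_claims_bundle,
)
from .cohort_selection import (
    CASE_REASONS,
    CONTROL_REASONS,
    SelectionConfig,
    select_cohort,
    selection_summary,
)
from .matching import MatchProblem, matchsets_frame, optimal_match, validate_matching
from .phenotyping import CodeLists, PhenotypeConfig, phenotype_cohort
from .survival import drfs_records, km_estimate, logrank, os_records, survival_at
from .synthetic_claims import (
    SYNTHETIC_CODE_LISTS,
    SyntheticConfig,
    generate_cohort,
    inject_coding_gaps,
    write_ground_truth,
)

__all__ = [
    "PipelineConfig",
    "percent",
    "baseline_table",
    "run_pipeline",
    "read_outcomes",
    "read_phenotypes",
    "read_matches",
]


def _read_csv_dates(path: Path, date_cols: tuple[str, ...], bool_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in date_cols:
        if col in df.columns:
            df[col] = df[col].map(lambda v: None if v == "" else date.fromisoformat(v))
    for col in bool_cols:
        if col in df.columns:
            df[col] = df[col] == "True"
    return df


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Read an exclusion-outcome artifact back (dates parsed)."""
    return _read_csv_dates(Path(path), ("index_date",))


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotypes.csv artifact back (dates and flags parsed)."""
    return _read_csv_dates(
        Path(path), ("index_date", "met_onset"),
        ("surgery", "radiation", "systemic_therapy"),
    )


def read_matches(path: str | Path):
    """Read a matches.csv artifact back into MatchSet objects."""
    from .matching import MatchSet

    df = pd.read_csv(Path(path), dtype={"case_id": str, "control_id": str, "age_diff": int})
    sets = []
    for cid, grp in df.groupby("case_id", sort=True):
        sets.append(MatchSet(case_id=cid,
                             control_ids=tuple(grp["control_id"]),
                             age_diffs=tuple(int(a) for a in grp["age_diff"])))
    return sets


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded to one decimal, half away from zero."""
    if denominator == 0:
        raise ClaimsError("percent() with zero denominator")
    value = Decimal(100 * numerator) / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def baseline_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics: receptor status, subtype, stage and
    treatment blocks with N and % of the cohort total.

    Receptor rows are sums of subtype rows by construction (HR+ =
    HR+/HER2+ plus HR+/HER2-), so the blocks stay mutually consistent.
    """
    total = len(phenotypes)
    rows: list[dict] = []

    def add(block: str, label: str, n: int):
        rows.append({"block": block, "row": label, "n": int(n),
                     "pct": percent(int(n), total)})

    sub = phenotypes["subtype"].value_counts()
    n_sub = {s: int(sub.get(s, 0)) for s in
             ("HR+/HER2+", "HR+/HER2-", "HR-/HER2+", "HR-/HER2-")}
    add("receptor", "HR+", n_sub["HR+/HER2+"] + n_sub["HR+/HER2-"])
    add("receptor", "HR-", n_sub["HR-/HER2+"] + n_sub["HR-/HER2-"])
    add("receptor", "HER2+", n_sub["HR+/HER2+"] + n_sub["HR-/HER2+"])
    add("receptor", "HER2-", n_sub["HR+/HER2-"] + n_sub["HR-/HER2-"])
    for s, n in n_sub.items():
        add("subtype", s, n)
    for s in ("A", "B", "C"):
        add("stage", s, (phenotypes["stage"] == s).sum())
    for block, col in (("breast_surgery", "surgery"), ("radiation_therapy", "radiation"),
                       ("systemic_therapy", "systemic_therapy")):
        n_yes = int(phenotypes[col].sum())
        add(block, "yes", n_yes)
        add(block, "no", total - n_yes)
    return pd.DataFrame(rows, columns=["block", "row", "n", "pct"])


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """Everything one reproducible pipeline run needs.

    Exactly one of ``synthetic`` / ``input_dir`` provides the claims
    tables.  ``code_lists`` must be given explicitly ("synthetic" selects
    the lists matching the generator's coding).
    """

    output_dir: str
    seed: int
    code_lists: CodeLists
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    selection: SelectionConfig = SelectionConfig()
    phenotype: PhenotypeConfig = PhenotypeConfig()
    ratio: int = 2
    n_split: int = 1
    horizons_days: tuple[int, ...] = (1825, 3650)
    control_index: str = "case_index"

    def __post_init__(self):
        if (self.synthetic is None) == (self.input_dir is None):
            raise ClaimsError("exactly one of synthetic/input_dir must be set")
        if list(self.horizons_days) != sorted(self.horizons_days) or min(self.horizons_days) <= 0:
            raise ClaimsError("horizons must be positive and ascending")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if "code_lists" not in raw:
            raise ClaimsError("pipeline config requires a code_lists section")
        cl = raw.pop("code_lists")
        if cl == "synthetic":
            code_lists = SYNTHETIC_CODE_LISTS
        else:
            code_lists = CodeLists(**{k: frozenset(v) for k, v in cl.items()})
        synthetic = raw.pop("synthetic", None)
        if synthetic is not None:
            synthetic = SyntheticConfig.from_dict(synthetic)
        selection = SelectionConfig(**_parse_dates(raw.pop("selection", {})))
        phenotype = PhenotypeConfig(**raw.pop("phenotype", {}))
        if "horizons_days" in raw:
            raw["horizons_days"] = tuple(raw["horizons_days"])
        return cls(code_lists=code_lists, synthetic=synthetic,
                   selection=selection, phenotype=phenotype, **raw)


def _parse_dates(d: dict) -> dict:
    out = dict(d)
    for key in ("index_window_start", "index_window_end"):
        if key in out and isinstance(out[key], str):
            out[key] = date.fromisoformat(out[key])
    if "neoplasia_excluded_prefixes" in out:
        out["neoplasia_excluded_prefixes"] = frozenset(out["neoplasia_excluded_prefixes"])
    return out


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _write(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == object:
            out[col] = out[col].map(
                lambda v: v.isoformat() if isinstance(v, date) else ("" if v is None else v)
            )
    out.to_csv(path, index=False)


def _km_export(records: pd.DataFrame, label_col: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-form curve table plus per-label curve objects (as dict)."""
    curve_rows, curves = [], {}
    for label, grp in records.groupby(label_col, sort=True):
        curve = km_estimate(grp)
        curves[label] = curve
        for t, nr, ne, s, se in zip(curve.times, curve.n_at_risk, curve.n_events,
                                    curve.survival, curve.se):
            curve_rows.append({"label": label, "time_days": t, "n_risk": int(nr),
                               "n_event": int(ne), "survival": s, "se": se})
    return pd.DataFrame(curve_rows, columns=["label", "time_days", "n_risk", "n_event", "survival", "se"]), curves


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Fully deterministic given the config (all randomness flows from the
    synthetic seed).  Any stage failure propagates annotated with the
    stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise ClaimsError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    # -- load or generate ---------------------------------------------------
    @stage("load")
    def bundle() -> ClaimsBundle:
        if config.synthetic is not None:
            clean, truth = generate_cohort(config.synthetic)
            noisy = inject_coding_gaps(clean, truth, config.synthetic)
            write_claims_bundle(noisy, out / "claims")
            write_ground_truth(truth, out / "claims")
            return noisy
        return load_claims_bundle(config.input_dir)

    for name, df in bundle.tables().items():
        log.append(f"load: {name} rows={len(df)}")

    # -- selection ----------------------------------------------------------
    @stage("select")
    def outcomes():
        return select_cohort(bundle, config.code_lists, config.selection, config.phenotype)

    case_outcomes, control_outcomes = outcomes
    included_cases = case_outcomes.loc[case_outcomes["status"] == "included"]
    eligible_controls = control_outcomes.loc[control_outcomes["status"] == "included"]
    log.append(f"select: cases included {len(included_cases)}/{len(case_outcomes)}")
    log.append(f"select: controls eligible {len(eligible_controls)}/{len(control_outcomes)}")
    _write(case_outcomes, out / "outcomes_cases.csv")

    # -- phenotyping --------------------------------------------------------
    @stage("phenotype")
    def phenotypes():
        index_dates = dict(zip(included_cases["patient_id"], included_cases["index_date"]))
        return phenotype_cohort(bundle, index_dates, config.code_lists, config.phenotype)

    _write(phenotypes, out / "phenotypes.csv")
    log.append(f"phenotype: {len(phenotypes)} cases")

    # -- matching -----------------------------------------------------------
    @stage("match")
    def matchsets():
        patients = bundle.patients.set_index("patient_id")
        cases = pd.DataFrame({
            "case_id": included_cases["patient_id"].to_numpy(),
            "birth_year": patients.loc[included_cases["patient_id"], "birth_year"].to_numpy(),
            "index_date": included_cases["index_date"].to_numpy(),
        })
        ins_end = {}
        for pid, grp in bundle.insurance.groupby("patient_id"):
            merged = merge_periods(list(zip(grp["start_date"], grp["end_date"])))
            ins_end[pid] = merged[-1][1]
        ctrl_ids = eligible_controls["patient_id"]
        controls = pd.DataFrame({
            "control_id": ctrl_ids.to_numpy(),
            "birth_year": patients.loc[ctrl_ids, "birth_year"].to_numpy(),
            "death_date": patients.loc[ctrl_ids, "death_date"].to_numpy(),
            "insurance_end": [ins_end.get(c) for c in ctrl_ids],
        })
        problem = MatchProblem(cases, controls, ratio=config.ratio, n_split=config.n_split)
        sets = optimal_match(problem)
        diagnostics = validate_matching(sets, problem)
        log.append(f"match: {diagnostics['n_matchsets']} sets, total cost {diagnostics['total_cost']}")
        hist = pd.DataFrame(
            [{"age_diff": k, "count": v} for k, v in diagnostics["age_diff_histogram"].items()]
        )
        _write(hist, out / "match_age_diff_histogram.csv")
        return sets

    _write(matchsets_frame(matchsets), out / "matches.csv")

    # matched controls finalize the control outcomes (unmatched -> excluded)
    matched_ids = {c for m in matchsets for c in m.control_ids}
    final_controls = control_outcomes.copy()
    unmatched = (final_controls["status"] == "included") & ~final_controls["patient_id"].isin(matched_ids)
    final_controls.loc[unmatched, ["status", "reason"]] = ["excluded", "unmatched"]
    _write(final_controls, out / "outcomes_controls.csv")
    _write(selection_summary(case_outcomes, CASE_REASONS), out / "selection_summary_cases.csv")
    _write(selection_summary(final_controls, CONTROL_REASONS), out / "selection_summary_controls.csv")

    # -- survival -----------------------------------------------------------
    @stage("survive")
    def survival_outputs():
        os_recs = os_records(phenotypes, matchsets, bundle, config.control_index)
        os_recs["label"] = [
            f"stage_{s.split('|')[0]}" if g == "case" else "control"
            for g, s in zip(os_recs["group"], os_recs["stratum"])
        ]
        _write(os_recs, out / "records_os.csv")
        curves_os, km_os = _km_export(os_recs, "label")
        _write(curves_os, out / "curves_os.csv")

        horizon_rows = []
        for label, curve in km_os.items():
            for h in config.horizons_days:
                at = survival_at(curve, h)
                horizon_rows.append({"label": label, "horizon_days": h,
                                     "survival": at.estimate, "se": at.se,
                                     "beyond_follow_up": at.beyond_follow_up})
        _write(pd.DataFrame(horizon_rows), out / "os_at_horizons.csv")

        lr_rows = [{"comparison": "os_all_groups", **dataclasses.asdict(logrank(os_recs, "label"))}]
        for s in ("A", "B", "C"):
            sub = os_recs.loc[os_recs["label"].isin([f"stage_{s}", "control"])]
            if sub["label"].nunique() == 2:
                lr_rows.append({"comparison": f"os_stage_{s}_vs_control",
                                **dataclasses.asdict(logrank(sub, "label"))})

        ab = phenotypes.loc[phenotypes["stage"].isin(["A", "B"])]
        if len(ab):
            drfs = drfs_records(ab, bundle)
            _write(drfs, out / "records_drfs.csv")
            curves_drfs, _ = _km_export(drfs, "stratum")
            _write(curves_drfs, out / "curves_drfs.csv")
            for s in ("A", "B"):
                sub = drfs.loc[drfs["stratum"].str.startswith(s)]
                if sub["stratum"].nunique() >= 2:
                    lr_rows.append({"comparison": f"drfs_stage_{s}_subtypes",
                                    **dataclasses.asdict(logrank(sub, "stratum"))})
        _write(pd.DataFrame(lr_rows), out / "logrank.csv")
        return None

    # -- report -------------------------------------------------------------
    @stage("report")
    def report():
        _write(baseline_table(phenotypes), out / "baseline_table.csv")
        (out / "run_log.txt").write_text("\n".join(log) + "\n")
        return None

    return out
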