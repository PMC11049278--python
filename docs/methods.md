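# Methods

## The disease model

`bcclaims` reconstructs a breast-cancer cohort from statutory-claims
tables in which no clinical variable is recorded directly.  Everything
rests on four coding conventions of German claims data:

* inpatient diagnoses are dated; outpatient diagnoses exist only at
  calendar-quarter resolution;
* a diagnosis is trustworthy when billed inpatient once, or repeatedly
  outpatient (the M2Q idea);
* filled prescriptions (ATC) reveal the therapy a patient actually
  received, hence — for breast cancer — the tumor biology it was
  prescribed for;
* procedures (OPS) mark surgery, radiation and biopsies.

From these the package derives: an index diagnosis date (first inpatient
C50), a distant-metastasis onset, a stage surrogate A/B/C, an HR/HER2
subtype surrogate, and treatment flags.  The stage labels are deliberate
surrogates, not TNM/UICC stages: they use only nodal (C77.3) and distant
spread, never tumor size or node counts.

### Metastasis onset

Direct coding of secondary neoplasms (C77–C79 minus C77.3/C77.9) is
taken at the inpatient date, or — outpatient — at the midpoint of the
first quarter of a run of at least `outpatient_consecutive_quarters`
consecutive coded quarters.  Because direct coding is often late or
absent, four proxy criteria fire on treatment patterns that essentially
only occur in metastatic disease:

| criterion | threshold | implied onset |
|---|---|---|
| chemotherapy | ≥ 5 distinct quarters | midpoint of the 5th |
| HER2-antibody therapy | ≥ 7 distinct quarters | midpoint of the 7th |
| metastasis-defining medication | ≥ 2 distinct quarters | midpoint of the 1st |
| histology of a putative malignant lesion | 1 procedure | its date |

The earliest candidate across all criteria wins; ties resolve in the
table's order.  Quarter counts for the therapy criteria use *distinct*
(not necessarily consecutive) quarters: maintenance therapy is routinely
billed with gaps, and the onset is defined by cumulative exposure, not
continuity.  Consecutiveness is required only for outpatient *diagnosis*
validation, where it guards against stray miscodes.

"Quarter midpoint" is quarter start + 45 days (configurable): quarters
span 90–92 days, so day 45 sits within a day of the true center, and a
date implied this way is at most 46 days from any true date in the
quarter.  That 46-day bound is the dating resolution of every
quarter-based criterion and is what the recovery tests assert.

### Stage

With index date `t0` and a 183-day window (the fixed reading of "6
months"): stage C iff a metastasis onset falls in `(t0−183, t0+183]`;
else stage B iff any C77.3 falls in `[t0, t0+183]`; else stage A.  The
stage-C window is two-sided because cohort selection has already
removed onsets ≥183 days *before* the index — an onset slightly before
the index is primary metastatic disease whose workup preceded the
inpatient admission.  Quarter-midpoint dating can move an onset near the
window edge across it (at most 46 days), so stage recovery under
proxy-only coding is exact only away from the boundary; the tests make
this explicit.

### Subtype

HR+ (HER2+) iff at least one endocrine (HER2-targeted) fill occurs
strictly after the index date and within the observation window.  GnRH
analogs are excluded from the endocrine set: in premenopausal patients
they are co-prescribed with chemotherapy for ovarian protection and
carry no receptor information.  This is a *prescription-defined*
subtype; a never-treated HR+ tumor is classified HR− by construction.

### Cohort selection

Candidates receive exactly one outcome, applying rules in a fixed
precedence (the attrition-table row order): unreliable C50 → index
outside [2010-07-01, 2019-12-31] → second primary → prior metastasis
(onset ≤ t0 − 183 d) → coverage < 40% → death before index → male sex.
Controls: second primary → metastasis at any time → missing/short
insurance → male sex; eligible controls are finalized by matching.  The
precedence is a modeling choice — one reason per patient implies *some*
order, and the table order is the only published one.  "Second primary"
means C-chapter codes minus C50 (the disease itself), C44 (non-melanoma
skin cancer, clinically negligible here) and C77–C79 (these code
metastatic spread, which the metastasis rules own; counting them as
second primaries would void stage C entirely).  Outpatient neoplasia
codes need two distinct quarters of the same 3-character code.

Coverage is (days insured ∩ observation window)/(window days), inclusive
on both ends — insurance is a whole-day membership.  The observation
window runs from 2010-01-01 to min(death, 2020-12-31).

### Matching

1:`ratio` (default 2) optimal matching minimizing the summed absolute
birth-year difference, with a hard caliper: a control who died or left
insurance on/before the case's index date is never pairable.  The
problem is a minimum-cost bipartite b-matching, solved exactly by
replicating each case row `ratio` times and running the
Jonker–Volgenant shortest-augmenting-path solver
(`scipy.optimize.linear_sum_assignment`) with forbidden pairs at
infinite cost.  Ties among equal-cost optima are broken deterministically
(an integer rank perturbation, scaled so its total can never offset one
unit of true cost, after canonical sorting by id) so results are
independent of input row order.  `n_split > 1` partitions cases and
controls round-robin by consecutive id and matches each part
independently — the historical workaround for memory limits; per-split
optimality holds, but the combined cost can exceed the unsplit optimum,
so the default is no splitting.

### Survival

OS: index to death, administratively censored at 2020-12-31 (deaths
reported later are known but lie outside the observation window; using
them would make censoring informative at the boundary).  Controls have
no index of their own; their clock starts at their matched case's index
date — the caliper guarantees they are alive and insured then — and
they inherit the case's stage/subtype stratum.  A switch
(`control_index="study_start"`) clocks controls from 2010-01-01 instead.
DRFS: index to first distant metastasis, defined for stages A/B only;
death without metastasis censors (no competing-risk treatment — DRFS is
defined purely as time to metastasis).

Curves are product-limit estimates (fitted via lifelines) carrying the
plain Greenwood standard error; where the curve reaches exactly 0 the
Greenwood formula degenerates and the SE is reported as 0.  Group
comparison is the unweighted log-rank test (χ², groups−1 df).

**A matched-design selection effect worth knowing.**  Matched-control
survival measured from the case index is *not* the marginal control
survival: controls who die mid-study satisfy the caliper only for
early-index cases, so any feasible matching routes them to early cases
while late-index cases absorb long-lived controls.  Under the default
synthetic hazard (0.036/yr, implying 83.5% marginal 5-year survival)
the matched-control 5-year OS comes out around 70–75%.  This is a
property of the design (any caliper-constrained matcher, including the
published procedure, shares it), verified here by recomputing survival
independently from the ground-truth tables.  The acceptance script
therefore reports both the matched-control estimate and a pool-level
estimate clocked from the study start, which recovers the generating
hazard cleanly.

## The synthetic-claims generator

The generator emulates the *observable structure* of the source
population: age-band distribution at diagnosis (0.160, 0.214, 0.227,
0.227, 0.171 for <50/50s/60s/70s/≥80), subtype prevalences (HR+/HER2+
0.069, HR+/HER2− 0.709, HR−/HER2+ 0.029, HR−/HER2− 0.192), stage
prevalences (A 0.678, B 0.170, C 0.152), and coding-defect rates at the
published attrition levels (outpatient-only C50 51.6%, second primaries
9.9% cases / 11.6% controls, short insurance 0.7% / 2.7%, male 1.7% /
1.2%).  The direct-metastasis-coding gap rate is unpublished and
defaults to 0.25.  Survival is exponential per (stage, subtype) with
rates honoring the observed ordering (stage A best, C worst;
triple-negative worst within each stage; defaults 0.035/0.06/0.30 per
year by stage times 0.8/1.0/1.1/1.6 by subtype; controls 0.036/yr —
chosen so control 5-year survival sits near the mid-80s); late
recurrence for stages A/B arrives at 0.02/0.05 per year after the
6-month window.  Stage-C metastasis dates are uniform on [index−30 d,
index+150 d], safely inside the stage window.

Gap injection replaces a stage-C case's direct coding with exactly one
proxy whose implied onset equals the truth quarter's midpoint: HER2+
cases get the antibody criterion (antibody therapy implies HER2+, and
the construction keeps the 7th distinct quarter at the onset quarter
even merged with the patient's own fills); others draw among chemo,
metastasis-defining medication and histology, falling back to the
date-exact histology proxy when the study era has too few quarters
before the onset.  The synthetic metastasis-defining medication class is
ATC V10 (therapeutic radiopharmaceuticals, e.g. radium-223 for bone
metastases) and the histology class OPS 1-56 (deep-organ biopsies);
the package-level defaults for these two lists are *empty* with a
warning, because no universal list is defensible — analysts must supply
their own, and all tests pass lists explicitly.

What the generator does **not** emulate: real billing semantics (DRG/EBM),
comorbidity, age-dependent background mortality, non-exponential hazards,
correlated coding behavior, or adherence below 100% (the truth subtypes
are calibrated to prescription-defined prevalences, so full adherence is
the self-consistent default; the knob exists for sensitivity analyses).
Passing recovery tests therefore demonstrates the *logic* of the
reconstruction rules, not their clinical accuracy on real data.

## Numerical and interface choices

* "6 months" = 183 days; "more than two consecutive calendar quarters"
  read literally as ≥3 (configurable; the common M2Q convention would
  be 2).
* Percentages round half away from zero to one decimal — the printed
  convention of the tables this layout mirrors; bankers' rounding would
  differ on ties.
* All dates ISO-8601 in files, `datetime.date` in memory; empty string
  means absent; bundles round-trip byte-identically.
* Degenerate inputs: empty record sets for KM raise; horizons beyond the
  last follow-up return the last value flagged; an empty outcome set
  yields an empty attrition table with total 0; infeasible matching
  splits raise naming the split and its deficit.
* Problem sizes: recovery runs use 2,000 cases (clean and proxy-coded),
  matching verification 200 random instances of ≤6 cases/≤14 controls
  against exhaustive enumeration, hazard recovery 20 replicates of
  n=5,000, and the end-to-end pipeline 800 cases with 2,400 control
  candidates — sizes at which every property under test is already
  exercised and the whole suite runs in well under a minute per check.

## Limitations

Prescription-defined subtypes misclassify untreated biology; stage
surrogates ignore tumor size; quarter-midpoint dating carries ±46-day
error into DRFS times; the exclusion precedence affects the attrition
table's composition (though not who is excluded); and the synthetic
population's joint structure beyond the published marginals is invented,
so real-data performance claims cannot be made from these tests.
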