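# hkpim

Tools around the Hong Kong-specific list of potentially inappropriate
medications (PIMs) for adults aged 65 or older: the machine-readable criteria
set, the modified-Delphi consensus engine that classifies expert panel
ratings, the multi-list candidate-selection rule the preliminary list was
built with, and a patient-level screening engine that applies the criteria to
medication/diagnosis records.

## Who this is for

Pharmacoepidemiologists and medication-safety researchers who want to

* measure PIM prevalence in cohorts of older adults coded with WHO ATC
  medication codes and a controlled condition vocabulary,
* reproduce or rerun the consensus methodology (Likert ratings summarised as
  median/IQR with threshold classification over two rounds), or
* build derived criteria sets with auditable provenance (printed vs curated
  ATC codes, errata, validation).

## The criteria and the consensus model

The packaged criteria set contains 172 statements: the 164-statement final
list — 77 *independent of diagnosis* (avoid regardless of conditions) and 87
*condition-specific* (avoid given a named condition, e.g. benzodiazepines in
dementia) — plus the 8 statements on which the expert panel reached no
consensus and which are therefore excluded from the final list.

Each statement carries the expert panel's rating summary. With ratings
`x_1..x_n` on a 1–5 Likert scale (5 = strongly agree the use is
inappropriate), the panel's consensus is summarised as the median `m` and the
interquartile range `[Q1, Q3]`, and classified

```
EXCLUDED      if  m < 3.0
INCLUDED      if  m ≥ 3.5  and  (Q3 − Q1) ≤ 1.5
QUESTIONABLE  otherwise
```

Round 1 rates all 168 preliminary candidates (8 raters); questionable
statements plus panel-suggested additions are re-rated in round 2 (7 raters
after one dropout). Quartiles are computed by linear interpolation of the
order statistics on exact rationals; nearest-rank and Tukey-hinge estimators
are available for sensitivity analysis.

Screening matches a patient's 7-character substance-level ATC codes against
statement codes hierarchically: exact equality, or class-prefix match when
the statement is class-level (e.g. patient `C02AB01` vs statement `C02AB`).
Condition-specific statements additionally require the statement's condition
among the patient's conditions.

## Worked example

```python
from hkpim import PatientRecord, load_default_criteria, screen_patient

criteria = load_default_criteria()
print(criteria.counts())
patient = PatientRecord(
    patient_id="demo", age_years=81,
    medications=["N05BA01"],                       # diazepam
    conditions=["dementia_cognitive_impairment"])
for f in screen_patient(patient, criteria):
    print(f.statement_id, f.matched_medication, f.match_level,
          f.matched_condition or "-")
```

prints

```
{'total': 172, 'independent_included': 77, 'condition_specific_included': 87,
 'questionable': 8, 'excluded': 0, 'final_included': 164}
IND049 N05BA01 EXACT -
CSP022 N05BA01 CLASS_PREFIX dementia_cognitive_impairment
```

i.e. diazepam triggers the diagnosis-independent diazepam statement (exact
substance match) and, because the patient has a dementia diagnosis, the
condition-specific "benzodiazepines in dementia/cognitive impairment"
statement (class-prefix match on `N05BA`).

The same pipeline is scriptable from the shell:

```
hkpim validate                       # fixture integrity + consensus audit
hkpim simulate --kind cohort --n 100 --pim-rate 0.4 --seed 7 --out demo
hkpim screen --patients demo.patients.json --out report.json
```

the last line logging
`100 patients screened; prevalence 40.0% (40 with >=1 PIM flag, ...)`.

## Layout

* `src/hkpim/criteria_model.py` — domain types, ATC grammar, criteria I/O,
  validation, packaged fixture
* `src/hkpim/delphi.py` — consensus statistics and round orchestration
* `src/hkpim/selection.py` — reference-list selection rule and formulary
  filtering
* `src/hkpim/screening.py` — hierarchical ATC matching and cohort reports
* `src/hkpim/synthetic_data.py` — generators with known ground truth
* `src/hkpim/cli.py` — `hkpim` command-line entry point
* `docs/methods.md` — modelling notes, parameter defaults, limitations
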