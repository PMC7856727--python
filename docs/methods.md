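# Methods notes

## Scope and model

The package implements an explicit (criterion-based) prescribing-quality tool
for adults aged 65+ in the Hong Kong public-sector context, in four stages:

1. **Candidate selection.** From an incidence table recording which of nine
   published reference criteria (McLeod, Rancourt, Lindblad, Laroche,
   Winit-Watjana, NORGEP, PRISCUS, STOPP v2, Beers 2015) list a medication or
   class, an entity becomes a candidate when it appears in ≥ 3 lists, or in
   exactly 2 of which one is Beers 2015. The Beers condition is read as
   applying only to the exactly-two case — a literal reading of the rule —
   so three non-Beers lists suffice. Candidates are then filtered by
   availability in the hospital-authority drug formulary, and class-level
   candidates expand to their formulary member substances.
2. **Consensus classification.** Experts rate each candidate's
   inappropriateness 1–5; per statement the ratings are summarised as median
   and interquartile range and classified: excluded if median < 3.0, included
   if median ≥ 3.5 and IQR width ≤ 1.5, questionable otherwise. Exclusion
   takes precedence when median < 3.0 and width > 1.5 hold simultaneously,
   because the exclusion rule is unconditional. Both boundary cases are
   resolved by the rule text: median exactly 3.0 is questionable, width
   exactly 1.5 satisfies inclusion.
3. **Two-round flow.** Round 1 rates the full preliminary list (8 raters);
   round-1 questionables plus panel-suggested additions are re-rated in round
   2 (7 raters after one dropout; missing ratings are omitted, never
   imputed). Statements still questionable after round 2 are dropped. The
   final list is the union of the two rounds' inclusions.
4. **Screening.** Patient substance-level ATC codes match statement codes
   exactly or by class prefix (statement code of length 1/3/4/5 that prefixes
   the patient code); condition-specific statements additionally require the
   coded condition. When a class statement and a more specific statement both
   match one medication, the most specific is the primary flag and the class
   match is kept but marked secondary, giving one actionable flag per drug
   per rule family.

## Quantile estimator

The consensus thresholds are quarter-step sensitive, so the quartile
definition matters. The default is linear interpolation of the order
statistics (the common spreadsheet/statistics default, `numpy` method
`linear`): the q-quantile sits at fractional position `q·(n−1)`. This is the
only one of the three implemented estimators that attains every quartile
printed in the packaged criteria — quarter-step values (2.75, 3.75, 4.25,
4.75) with 8 raters and half-step values with 7 — which the test suite
verifies by exhaustively enumerating all integer rating multisets (at most
C(n+4,4) = 495 for n = 8) and inverting each printed summary. Nearest-rank
and Tukey-hinge estimators are selectable for sensitivity analysis. All
quantile arithmetic runs on exact rationals (`fractions.Fraction`);
thresholds are compared exactly, never with float tolerances.

## The packaged criteria fixture

`src/hkpim/data/criteria_hk.csv` transcribes the published tables: 77
diagnosis-independent statements, 87 condition-specific statements, and the
8 questionable statements excluded after round 2 (172 rows; the 164-row
final list is the INCLUDED subset). Transcription decisions:

* **Printed vs curated ATC codes.** The five panel-suggested
  diagnosis-independent rows are printed with ATC codes shifted against
  their drug names (acetaminophen carries methadone's code, and so on).
  The printed codes are stored verbatim in `atc_code_printed`; matching uses
  `atc_code_curated`, set to the pharmacologically correct code, with one
  erratum row each recording the change and its rationale. Curated codes
  are this package's inference, not an assertion of the authors' intent.
* **Condition-specific codes.** The condition-specific table prints class
  names without codes; the fixture assigns one representative class-level
  code per row (benzodiazepines → N05BA, tricyclic antidepressants → N06AA,
  NSAIDs → M01A, beta blockers → C07, corticosteroids → H02AB systemic,
  anticholinergics → A03B, …). Pharmacological groups spanning several ATC
  branches are therefore matched only on the representative branch — a known
  limitation; extend the fixture with additional rows to widen coverage.
* **The duplicated analgesic rows.** Acetaminophen and methyl salicylate
  topical ointment appear both among the questionable statements and in the
  final independent-of-diagnosis table with medians of 3. They are
  transcribed in both places as printed; `validate_criteria` reports the two
  final-list rows as warnings (their summaries fail the inclusion rule), and
  errata cover them so strict validation still passes. The headline count of
  77 counts the final table as printed.
* **Decided round.** The tables do not state which round settled most rows.
  The fixture marks the questionable statements, the panel-suggested rows,
  and the three round-2 indication additions (antihypertensive terazosin,
  urological doxazosin and prazosin) as round 2; every other row defaults to
  round 1 unless its printed summary is provably unattainable with 8 raters
  under linear interpolation (e.g. any Q3 of 4.50), in which case round 2.
  The assignment is verified exhaustively at build time and by the tests;
  it is a low-confidence reconstruction where the tables are silent.
* **Conditions.** Condition identifiers are lower-snake-case tokens derived
  from the printed disease/syndrome labels (`chronic_kidney_disease`, …);
  `conditions_hk.csv` maps tokens to labels. No ICD mapping is attempted.
* **Statement ids** are deterministic: `IND`/`CSP` plus the zero-padded
  ordinal in table order for the final list, `QIN`/`QCS` for the
  questionable statements.

## Synthetic data

The generators define the conditions under which the pipeline is exercised:

* `gen_ratings`/`gen_panel` invert consensus summaries by exhaustive multiset
  enumeration — deterministic and complete, so an "unreachable" error is a
  proof, not a sampling failure. Panel sizes follow the study: 8 raters for
  round-1 decisions, 7 for round 2. Round-count simulations use the study's
  own arithmetic (168 = 78 + 90 preliminary candidates; round 2 = 43
  carried questionables + 3 indications + 9 new candidates = 55, of which 47
  reach consensus). The published text elsewhere says "44 plus 12" for round
  2, which sums to 56; the component sums (55) are used throughout.
* `gen_patients` plants a flaggable medication (and condition, for
  condition-specific statements) in exactly `round(n · pim_rate)` patients —
  default rate 0.4, within the locally reported prevalence range — and fills
  the rest with codes rejection-sampled to match nothing, so prevalence and
  the flag set are known exactly. Ages are uniform 65–95, medications per
  patient uniform 1–5. The cohorts carry no co-prescription correlation,
  dosing, or longitudinal structure: passing tests show the matcher is
  correct, not that real-world prevalence estimates will be well calibrated.
* `gen_reference_matrix` draws 1–4 list memberships per entity and computes
  the expected selection with its own copy of the rule, independent of the
  selection module.

All generators are pure functions of (spec, seed).

## Numerical and degenerate-input choices

* Ratings are validated integers 1–5; an empty rating vector is an error.
* A rating matrix cell may be missing (panelist dropout); a statement must
  retain ≥ 1 rating.
* `classify_statement` is total on median ∈ [1,5] × width ∈ [0,4] and
  rejects out-of-range input rather than clamping.
* Criteria I/O is round-trip exact (CSV and JSON, UTF-8); loading validates
  every row and fails on the first violation with row and field named.
* An empty cohort has no defined prevalence and is rejected; duplicate
  patient ids are rejected; unknown condition tokens are warned about and
  ignored. Patients under the age threshold (default 65) are screened but
  listed as out-of-population.

## Problem sizes

The test suite and the acceptance script run at the study's own scale — the
largest simulated objects are a 168-statement × 8-expert panel, a
200-patient synthetic cohort, and exhaustive enumerations of ≤ 715 rating
multisets per statement — so a full run completes in seconds on one CPU.

## Known limitations

* Single representative ATC code per statement (see above): multi-branch
  drug classes are under-matched; drug–drug interactions and therapeutic
  duplication are out of scope by design of the source criteria.
* Dose, duration, and route qualifiers live in free-text `concerns`, not in
  structured fields, so screening cannot condition on them.
* Round-1 rating vectors were never published; round-level counts are
  reproduced generator-driven (by construction), not data-driven.
* The formulary fixture used in tests is synthetic; the real formulary
  contents are not redistributed.
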