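"""Patient-level PIM screening against a criteria set.

Each patient carries substance-level (7-character) ATC medication codes and
controlled-vocabulary condition tokens. A diagnosis-independent statement
flags a medication when its curated ATC code equals the medication code or is
a proper class-level prefix of it; a condition-specific statement additionally
requires the statement's condition among the patient's conditions.

When both a class-level and a substance-level statement match the same
medication, the most specific statement (longest matching code) is the primary
flag and broader class matches are recorded as secondary, so one drug yields
one actionable flag per rule family.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .criteria_model import Category, CriteriaSet, is_valid_atc

__all__ = [
    "MatchLevel",
    "PatientRecord",
    "Flag",
    "ScreeningReport",
    "ScreeningOptions",
    "match_atc",
    "screen_patient",
    "screen_cohort",
    "load_cohort",
    "write_report",
]

logger = logging.getLogger(__name__)

EXACT = "EXACT"
CLASS_PREFIX = "CLASS_PREFIX"
MatchLevel = str  # EXACT | CLASS_PREFIX


@dataclass
class PatientRecord:
    patient_id: str
    age_years: int
    medications: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for code in self.medications:
            if not is_valid_atc(code, substance_only=True):
                raise ValueError(
                    f"patient {self.patient_id!r}: medication {code!r} is not "
                    f"a substance-level (7-character) ATC code")


@dataclass
class Flag:
    patient_id: str
    statement_id: str
    matched_medication: str
    match_level: MatchLevel
    matched_condition: str
    category: Category
    secondary: bool = False

    def key(self) -> tuple[str, str, str, str]:
        return (self.patient_id, self.statement_id,
                self.matched_medication, self.matched_condition)


@dataclass
class ScreeningOptions:
    include_questionable: bool = False
    age_threshold: int = 65


@dataclass
class ScreeningReport:
    flags: list[Flag]
    patients: list[str]
    any_pim: dict[str, bool]
    out_of_population: list[str]
    statement_hits: dict[str, int]

    @property
    def prevalence(self) -> float:
        """Fraction of patients with at least one flag."""
        if not self.patients:
            raise ValueError("empty cohort has no prevalence")
        return sum(self.any_pim.values()) / len(self.patients)


def match_atc(patient_code: str, statement_code: str) -> Optional[MatchLevel]:
    """Hierarchical ATC match of a substance code against a statement code.

    Returns ``EXACT`` for equal codes, ``CLASS_PREFIX`` when the statement
    code is a proper class-level prefix (length 1, 3, 4 or 5) of the patient
    code, else ``None``.
    """
    if not is_valid_atc(patient_code, substance_only=True):
        raise ValueError(f"invalid patient ATC code {patient_code!r}")
    if not is_valid_atc(statement_code):
        raise ValueError(f"invalid statement ATC code {statement_code!r}")
    if patient_code == statement_code:
        return EXACT
    if len(statement_code) < 7 and patient_code.startswith(statement_code):
        return CLASS_PREFIX
    return None


def screen_patient(
    p: PatientRecord,
    cs: CriteriaSet,
    include_questionable: bool = False,
    options: Optional[ScreeningOptions] = None,
    known_conditions: Optional[set[str]] = None,
) -> list[Flag]:
    """All statement matches for one patient, deduplicated.

    One flag per (statement, medication) for diagnosis-independent statements
    and per (statement, medication, condition) for condition-specific ones.
    Unknown condition tokens are warned about and ignored. Patients under the
    age threshold are still screened; cohort reports mark them out-of-population.
    """
    opts = options or ScreeningOptions(include_questionable=include_questionable)
    statements = cs.included(include_questionable=opts.include_questionable)

    conditions = []
    for c in p.conditions:
        if known_conditions is not None and c not in known_conditions:
            logger.warning("patient %s: unknown condition token %r ignored",
                           p.patient_id, c)
            continue
        conditions.append(c)
    cond_set = set(conditions)

    raw: list[tuple[Flag, int]] = []  # flag + statement code length
    seen: set[tuple] = set()
    for med in p.medications:
        for s in statements:
            level = match_atc(med, s.atc_code_curated)
            if level is None:
                continue
            if s.category is Category.CONDITION_SPECIFIC:
                if s.condition_id not in cond_set:
                    continue
                cond = s.condition_id
            else:
                cond = ""
            f = Flag(patient_id=p.patient_id, statement_id=s.statement_id,
                     matched_medication=med, match_level=level,
                     matched_condition=cond, category=s.category)
            if f.key() in seen:
                continue
            seen.add(f.key())
            raw.append((f, len(s.atc_code_curated)))

    # most specific statement per (medication, condition, category) is primary
    best: dict[tuple, int] = {}
    for f, code_len in raw:
        k = (f.matched_medication, f.matched_condition, f.category)
        best[k] = max(best.get(k, 0), code_len)
    for f, code_len in raw:
        k = (f.matched_medication, f.matched_condition, f.category)
        if code_len < best[k]:
            f.secondary = True
    return [f for f, _ in raw]


def screen_cohort(
    records: Sequence[PatientRecord],
    cs: CriteriaSet,
    options: Optional[ScreeningOptions] = None,
    known_conditions: Optional[set[str]] = None,
) -> ScreeningReport:
    """Screen a cohort; prevalence = fraction of patients with >= 1 flag."""
    if not records:
        raise ValueError("empty cohort")
    opts = options or ScreeningOptions()
    ids = [r.patient_id for r in records]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"duplicate patient_id(s): {sorted(dup)}")
    flags: list[Flag] = []
    any_pim: dict[str, bool] = {}
    out_of_pop: list[str] = []
    hits: dict[str, int] = {}
    for r in records:
        pf = screen_patient(r, cs, options=opts,
                            known_conditions=known_conditions)
        flags.extend(pf)
        any_pim[r.patient_id] = bool(pf)
        if r.age_years < opts.age_threshold:
            out_of_pop.append(r.patient_id)
        for f in pf:
            hits[f.statement_id] = hits.get(f.statement_id, 0) + 1
    return ScreeningReport(flags=flags, patients=ids, any_pim=any_pim,
                           out_of_population=out_of_pop, statement_hits=hits)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_cohort(meds_path, conditions_path=None) -> list[PatientRecord]:
    """Read a cohort from long-form CSVs or a single JSON document.

    CSV: medications file with columns patient_id, age, atc_code; optional
    conditions file with columns patient_id, condition_id.
    JSON: list of objects {patient_id, age_years, medications, conditions}.
    """
    meds_path = Path(meds_path)
    if meds_path.suffix.lower() == ".json":
        doc = json.loads(meds_path.read_text(encoding="utf-8"))
        return [PatientRecord(
            patient_id=str(r["patient_id"]),
            age_years=int(r["age_years"]),
            medications=list(r.get("medications", [])),
            conditions=list(r.get("conditions", []))) for r in doc]
    df = pd.read_csv(meds_path, dtype=str, keep_default_na=False)
    ages: dict[str, int] = {}
    meds: dict[str, list[str]] = {}
    for rec in df.to_dict("records"):
        pid = rec["patient_id"]
        ages[pid] = int(float(rec["age"]))
        meds.setdefault(pid, [])
        code = rec.get("atc_code", "").strip()
        if code:
            meds[pid].append(code)
    conds: dict[str, list[str]] = {pid: [] for pid in ages}
    if conditions_path is not None:
        cdf = pd.read_csv(Path(conditions_path), dtype=str,
                          keep_default_na=False)
        for rec in cdf.to_dict("records"):
            conds.setdefault(rec["patient_id"], []).append(rec["condition_id"])
    return [PatientRecord(pid, ages[pid], meds[pid], conds.get(pid, []))
            for pid in ages]


def write_report(report: ScreeningReport, path, format: str = "json") -> None:
    """Write a screening report as JSON (machine) or TSV (human)."""
    path = Path(path)
    if format == "json":
        doc = {
            "n_patients": len(report.patients),
            "prevalence": report.prevalence,
            "out_of_population": report.out_of_population,
            "statement_hits": report.statement_hits,
            "flags": [
                {**asdict(f), "category": f.category.value}
                for f in report.flags
            ],
        }
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    cols = ["patient_id", "statement_id", "matched_medication", "match_level",
            "matched_condition", "category", "secondary"]
    rows = [{**asdict(f), "category": f.category.value} for f in report.flags]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
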