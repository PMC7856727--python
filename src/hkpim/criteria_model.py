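"""Domain model for explicit PIM (potentially inappropriate medication) criteria.

A criteria set is an ordered collection of statements, each naming a medication
or medication class (by WHO ATC code), optionally a medical condition, the
expert-panel consensus summary (median and interquartile range of 1-5 Likert
ratings), and a status (included in the final list, questionable, or excluded).

Two operational categories are modelled:

* ``INDEPENDENT`` — medications/classes to be generally avoided in older adults
  regardless of diagnosis;
* ``CONDITION_SPECIFIC`` — medications/classes to be avoided in patients known
  to have a specific medical condition (drug-disease interactions).

The module also ships the packaged Hong Kong-specific criteria fixture
(164 final statements: 77 independent + 87 condition-specific, plus the 8
questionable statements the panel did not reach consensus on) together with an
errata table recording curated corrections to internally inconsistent printed
values.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "Category",
    "Status",
    "Origin",
    "Severity",
    "ATC_LEVELS",
    "atc_level",
    "is_valid_atc",
    "PIMStatement",
    "ErratumNote",
    "CriteriaSet",
    "ValidationFinding",
    "ValidationReport",
    "CriteriaValidationError",
    "load_criteria",
    "write_criteria",
    "validate_criteria",
    "load_default_criteria",
    "load_condition_vocabulary",
]


# ---------------------------------------------------------------------------
# Enums
# ---------------------------------------------------------------------------

class Category(str, Enum):
    """Operational PIM category."""

    INDEPENDENT = "INDEPENDENT"
    CONDITION_SPECIFIC = "CONDITION_SPECIFIC"


class Status(str, Enum):
    """Consensus outcome for a statement."""

    INCLUDED = "INCLUDED"
    QUESTIONABLE = "QUESTIONABLE"
    EXCLUDED = "EXCLUDED"


class Origin(str, Enum):
    """Provenance of a statement within the Delphi process."""

    PRELIMINARY = "PRELIMINARY"
    PANEL_SUGGESTED = "PANEL_SUGGESTED"


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


# ---------------------------------------------------------------------------
# ATC code grammar
# ---------------------------------------------------------------------------

#: WHO ATC hierarchy: code length -> level (1 anatomical main group,
#: 2 therapeutic subgroup, 3 pharmacological subgroup, 4 chemical subgroup,
#: 5 chemical substance).
ATC_LEVELS = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}

_ATC_PATTERNS = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z][0-9]{2}$"),
    4: re.compile(r"^[A-Z][0-9]{2}[A-Z]$"),
    5: re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}$"),
    7: re.compile(r"^[A-Z][0-9]{2}[A-Z]{2}[0-9]{2}$"),
}


def atc_level(code: str) -> int:
    """Return the ATC hierarchy level (1-5) of ``code``.

    Raises ``ValueError`` if the code does not conform to the WHO ATC
    structure (valid lengths are 1, 3, 4, 5 and 7 characters).
    """
    if not is_valid_atc(code):
        raise ValueError(f"invalid ATC code: {code!r}")
    return ATC_LEVELS[len(code)]


def is_valid_atc(code: str, substance_only: bool = False) -> bool:
    """Check ``code`` against the ATC grammar.

    With ``substance_only=True`` only 7-character substance-level codes pass.
    """
    if not isinstance(code, str):
        return False
    pat = _ATC_PATTERNS.get(len(code))
    if pat is None:
        return False
    if substance_only and len(code) != 7:
        return False
    return bool(pat.match(code))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class CriteriaValidationError(ValueError):
    """Raised when a criteria file violates the statement invariants."""


@dataclass
class PIMStatement:
    """One criteria row.

    ``atc_code_printed`` preserves the source table verbatim (it may be wrong
    or empty); ``atc_code_curated`` is the code actually used for matching and
    must always pass the ATC grammar. When the two differ, an
    :class:`ErratumNote` in the owning set records why.
    """

    statement_id: str
    category: Category
    class_name: str
    medication_name: str
    atc_code_printed: str
    atc_code_curated: str
    condition_id: str
    median: float
    iqr_low: float
    iqr_high: float
    status: Status
    origin: Origin
    decided_round: int
    concerns: str = ""
    alternatives: list[str] = field(default_factory=list)

    def violations(self) -> list[tuple[str, str]]:
        """Return (field, message) pairs for every violated invariant."""
        out: list[tuple[str, str]] = []
        if not self.statement_id:
            out.append(("statement_id", "empty statement_id"))
        for name in ("median", "iqr_low", "iqr_high"):
            v = getattr(self, name)
            if not (1.0 <= v <= 5.0):
                out.append((name, f"{name}={v} outside [1, 5]"))
        if self.iqr_low > self.iqr_high:
            out.append(("iqr_low", f"Q1 > Q3 ({self.iqr_low} > {self.iqr_high})"))
        elif not (self.iqr_low <= self.median <= self.iqr_high):
            out.append(("median", f"median {self.median} outside IQR "
                                  f"[{self.iqr_low}, {self.iqr_high}]"))
        if round(self.median * 2) != self.median * 2:
            out.append(("median", f"median {self.median} not on a 0.5 grid"))
        if not is_valid_atc(self.atc_code_curated):
            out.append(("atc_code_curated",
                        f"malformed ATC code {self.atc_code_curated!r}"))
        if self.category is Category.CONDITION_SPECIFIC and not self.condition_id:
            out.append(("condition_id",
                        "condition-specific statement without condition_id"))
        if self.category is Category.INDEPENDENT and self.condition_id:
            out.append(("condition_id",
                        "diagnosis-independent statement carries a condition_id"))
        if self.decided_round not in (1, 2):
            out.append(("decided_round", f"decided_round={self.decided_round}"))
        return out

    @property
    def iqr_width(self) -> float:
        return self.iqr_high - self.iqr_low


@dataclass
class ErratumNote:
    """A curated correction of a printed field, with auditable rationale."""

    statement_id: str
    field_name: str
    printed_value: str
    curated_value: str
    rationale: str


@dataclass
class CriteriaSet:
    """An ordered, named collection of PIM statements with errata."""

    name: str
    statements: list[PIMStatement] = field(default_factory=list)
    errata: list[ErratumNote] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.statements)

    def __iter__(self):
        return iter(self.statements)

    def get(self, statement_id: str) -> PIMStatement:
        for s in self.statements:
            if s.statement_id == statement_id:
                return s
        raise KeyError(statement_id)

    def counts(self) -> dict[str, int]:
        """Headline counts by category and status."""
        c = {
            "total": len(self.statements),
            "independent_included": 0,
            "condition_specific_included": 0,
            "questionable": 0,
            "excluded": 0,
        }
        for s in self.statements:
            if s.status is Status.INCLUDED:
                if s.category is Category.INDEPENDENT:
                    c["independent_included"] += 1
                else:
                    c["condition_specific_included"] += 1
            elif s.status is Status.QUESTIONABLE:
                c["questionable"] += 1
            else:
                c["excluded"] += 1
        c["final_included"] = (c["independent_included"]
                               + c["condition_specific_included"])
        return c

    def included(self, include_questionable: bool = False) -> list[PIMStatement]:
        keep = {Status.INCLUDED}
        if include_questionable:
            keep.add(Status.QUESTIONABLE)
        return [s for s in self.statements if s.status in keep]

    def errata_for(self, statement_id: str) -> list[ErratumNote]:
        return [e for e in self.errata if e.statement_id == statement_id]


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass
class ValidationFinding:
    severity: Severity
    statement_id: str
    field_name: str
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity is Severity.ERROR]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity is Severity.WARNING]

    def ok(self) -> bool:
        return not self.errors

    def __len__(self) -> int:
        return len(self.findings)


def validate_criteria(cs: CriteriaSet, strict: bool = False) -> ValidationReport:
    """Check every statement invariant plus cross-row uniqueness.

    An INCLUDED statement whose printed (median, IQR width) fails the
    consensus rule (median >= 3.5 and width <= 1.5) is reported as a WARNING;
    in ``strict`` mode such a finding escalates to an ERROR unless an
    :class:`ErratumNote` covers the statement.
    """
    from .delphi import DelphiConfig, classify_statement  # local: avoid cycle

    report = ValidationReport()
    seen: set[str] = set()
    cfg = DelphiConfig()
    for s in cs.statements:
        for fname, msg in s.violations():
            report.findings.append(
                ValidationFinding(Severity.ERROR, s.statement_id, fname, msg))
        if s.statement_id in seen:
            report.findings.append(ValidationFinding(
                Severity.ERROR, s.statement_id, "statement_id",
                "duplicate statement_id"))
        seen.add(s.statement_id)
        # printed code only needs to parse when no erratum covers the row
        if (s.atc_code_printed and not is_valid_atc(s.atc_code_printed)
                and not cs.errata_for(s.statement_id)):
            report.findings.append(ValidationFinding(
                Severity.ERROR, s.statement_id, "atc_code_printed",
                f"malformed printed ATC code {s.atc_code_printed!r} "
                f"without erratum"))
        if s.status is Status.INCLUDED:
            cls = classify_statement(s.median, s.iqr_width, cfg)
            if cls is not Status.INCLUDED:
                covered = bool(cs.errata_for(s.statement_id))
                sev = Severity.ERROR if (strict and not covered) else Severity.WARNING
                report.findings.append(ValidationFinding(
                    sev, s.statement_id, "status",
                    f"status INCLUDED but consensus rule gives {cls.value} "
                    f"(median={s.median}, IQR width={s.iqr_width})"
                    + ("" if covered else "; no erratum coverage")))
    for e in cs.errata:
        if e.statement_id not in seen:
            report.findings.append(ValidationFinding(
                Severity.ERROR, e.statement_id, "statement_id",
                "erratum refers to unknown statement_id"))
    return report


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

_COLUMNS = [
    "statement_id", "category", "class_name", "medication_name",
    "atc_code_printed", "atc_code_curated", "condition_id",
    "median", "iqr_low", "iqr_high", "status", "origin",
    "decided_round", "concerns", "alternatives",
]

_ERRATA_COLUMNS = [
    "statement_id", "field_name", "printed_value", "curated_value", "rationale",
]


def _row_to_statement(row: dict, rowno: int) -> PIMStatement:
    def txt(key: str) -> str:
        v = row.get(key, "")
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        return str(v)

    def num(key: str) -> float:
        try:
            return float(row[key])
        except (KeyError, TypeError, ValueError) as exc:
            raise CriteriaValidationError(
                f"row {rowno}: field {key!r}: not a number ({row.get(key)!r})"
            ) from exc

    try:
        category = Category(txt("category"))
        status = Status(txt("status"))
        origin = Origin(txt("origin"))
    except ValueError as exc:
        raise CriteriaValidationError(f"row {rowno}: {exc}") from exc
    alternatives = [a for a in txt("alternatives").split("|") if a]
    stmt = PIMStatement(
        statement_id=txt("statement_id"),
        category=category,
        class_name=txt("class_name"),
        medication_name=txt("medication_name"),
        atc_code_printed=txt("atc_code_printed"),
        atc_code_curated=txt("atc_code_curated"),
        condition_id=txt("condition_id"),
        median=num("median"),
        iqr_low=num("iqr_low"),
        iqr_high=num("iqr_high"),
        status=status,
        origin=origin,
        decided_round=int(num("decided_round")),
        concerns=txt("concerns"),
        alternatives=alternatives,
    )
    bad = stmt.violations()
    if bad:
        fname, msg = bad[0]
        raise CriteriaValidationError(
            f"row {rowno} (statement {stmt.statement_id!r}), field {fname!r}: {msg}")
    return stmt


def _statement_to_row(s: PIMStatement) -> dict:
    d = asdict(s)
    d["category"] = s.category.value
    d["status"] = s.status.value
    d["origin"] = s.origin.value
    d["alternatives"] = "|".join(s.alternatives)
    return {k: d[k] for k in _COLUMNS}


def _errata_path_for(path: Path) -> Path:
    return path.with_suffix(".errata.csv")


def load_criteria(path, format: Optional[str] = None,
                  errata_path=None, name: Optional[str] = None) -> CriteriaSet:
    """Load a criteria set from CSV or JSON.

    CSV errata live in a sibling ``<stem>.errata.csv`` file (or at
    ``errata_path``); JSON files carry errata inline under an ``"errata"`` key.
    Every row is validated on load; the first violation raises
    :class:`CriteriaValidationError` naming the row and field.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    name = name or path.stem
    if format == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        rows = doc.get("statements", [])
        statements = [_row_to_statement(r, i + 1) for i, r in enumerate(rows)]
        errata = [ErratumNote(**{k: str(e.get(k, "")) for k in _ERRATA_COLUMNS})
                  for e in doc.get("errata", [])]
        return CriteriaSet(doc.get("name", name), statements, errata)
    if format != "csv":
        raise ValueError(f"unknown criteria format {format!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    statements = [_row_to_statement(row, i + 1)
                  for i, row in enumerate(df.to_dict("records"))]
    errata: list[ErratumNote] = []
    epath = Path(errata_path) if errata_path else _errata_path_for(path)
    if epath.exists():
        edf = pd.read_csv(epath, dtype=str, keep_default_na=False)
        errata = [ErratumNote(**{k: r.get(k, "") for k in _ERRATA_COLUMNS})
                  for r in edf.to_dict("records")]
    return CriteriaSet(name, statements, errata)


def write_criteria(cs: CriteriaSet, path, format: Optional[str] = None) -> None:
    """Write ``cs`` so that :func:`load_criteria` reproduces it field-for-field."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "json":
        doc = {
            "name": cs.name,
            "statements": [_statement_to_row(s) for s in cs.statements],
            "errata": [asdict(e) for e in cs.errata],
        }
        path.write_text(json.dumps(doc, ensure_ascii=False, indent=1),
                        encoding="utf-8")
        return
    if format != "csv":
        raise ValueError(f"unknown criteria format {format!r}")
    df = pd.DataFrame([_statement_to_row(s) for s in cs.statements],
                      columns=_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")
    if cs.errata:
        edf = pd.DataFrame([asdict(e) for e in cs.errata],
                           columns=_ERRATA_COLUMNS)
        edf.to_csv(_errata_path_for(path), index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------

def _data_path(filename: str) -> Path:
    return Path(resources.files("hkpim") / "data" / filename)


def load_default_criteria() -> CriteriaSet:
    """Load the packaged Hong Kong-specific criteria set.

    The set holds 172 statements: the 164-item final list (77 independent of
    diagnosis + 87 condition-specific) plus the 8 questionable statements the
    panel excluded after round 2, with errata for the curated ATC codes.
    """
    return load_criteria(_data_path("criteria_hk.csv"),
                         errata_path=_data_path("criteria_hk.errata.csv"),
                         name="hk_pim_2021")


def load_condition_vocabulary() -> dict[str, str]:
    """Controlled condition vocabulary: token -> human-readable label."""
    df = pd.read_csv(_data_path("conditions_hk.csv"), dtype=str,
                     keep_default_na=False)
    return dict(zip(df["condition_id"], df["label"]))
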