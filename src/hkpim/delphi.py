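"""Two-round modified-Delphi consensus engine.

Experts rate each candidate statement on a 5-point Likert scale (1 = strongly
disagree that the medication is inappropriate, 5 = strongly agree, 3 =
neutral). Per statement, the panel's ratings are summarised as median and
interquartile range (IQR) and classified:

* ``EXCLUDED``     — median < 3.0
* ``INCLUDED``     — median >= 3.5 and IQR width (Q3 - Q1) <= 1.5
* ``QUESTIONABLE`` — otherwise (3.0 <= median < 3.5, or IQR width > 1.5)

Round 1 rates the full preliminary candidate list; its questionable
statements, together with panel-suggested new candidates and indications, are
re-rated in round 2 by the remaining panel. Statements still questionable
after round 2 are dropped from the final list.

Quartiles are computed on exact rationals (``fractions.Fraction``) so that the
0.25-step arithmetic of 7/8-rater panels never suffers binary-float error.
The quantile method is configurable; linear interpolation of the empirical
CDF (the common spreadsheet default) is used unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .criteria_model import (
    Category,
    CriteriaSet,
    Origin,
    PIMStatement,
    Status,
)

__all__ = [
    "QUANTILE_METHODS",
    "DelphiConfig",
    "RatingMatrix",
    "ConsensusResult",
    "RoundResult",
    "compute_consensus",
    "classify_statement",
    "run_round",
    "assemble_final_list",
    "load_rating_matrix",
    "write_rating_matrix",
]

QUANTILE_METHODS = ("linear_interpolation", "nearest_rank", "tukey_hinges")


@dataclass
class DelphiConfig:
    """Consensus thresholds and the quantile estimator.

    ``exclude_median_max`` is an exclusive upper bound (median strictly below
    it excludes); ``include_median_min`` and ``iqr_max`` are inclusive.
    """

    include_median_min: float = 3.5
    exclude_median_max: float = 3.0
    iqr_max: float = 1.5
    quantile_method: str = "linear_interpolation"

    def __post_init__(self) -> None:
        if not (1 <= self.exclude_median_max <= self.include_median_min <= 5):
            raise ValueError("need 1 <= exclude_median_max <= "
                             "include_median_min <= 5")
        if self.iqr_max < 0:
            raise ValueError("iqr_max must be >= 0")
        if self.quantile_method not in QUANTILE_METHODS:
            raise ValueError(f"unknown quantile method "
                             f"{self.quantile_method!r}; "
                             f"choose from {QUANTILE_METHODS}")


@dataclass
class ConsensusResult:
    median: float
    q1: float
    q3: float
    iqr_width: float
    classification: Status

    def summary(self) -> tuple[float, float, float]:
        return (self.median, self.q1, self.q3)


@dataclass
class RoundResult:
    """Partition of one round's candidates by consensus outcome."""

    round_no: int
    included: list[str]
    excluded: list[str]
    questionable: list[str]
    results: dict[str, ConsensusResult]

    @property
    def candidates(self) -> list[str]:
        return self.included + self.excluded + self.questionable

    def sizes(self) -> dict[str, int]:
        return {
            "candidates": len(self.results),
            "included": len(self.included),
            "excluded": len(self.excluded),
            "questionable": len(self.questionable),
        }


# ---------------------------------------------------------------------------
# Quantiles on exact rationals
# ---------------------------------------------------------------------------

def _quantile(sorted_vals: Sequence[int], q: Fraction, method: str) -> Fraction:
    n = len(sorted_vals)
    if n == 0:
        raise ValueError("empty rating vector")
    if method == "linear_interpolation":
        # value at fractional position q*(n-1) of the order statistics
        pos = q * (n - 1)
        i = math.floor(pos)
        frac = pos - i
        lo = Fraction(sorted_vals[i])
        if frac == 0:
            return lo
        hi = Fraction(sorted_vals[i + 1])
        return lo + frac * (hi - lo)
    if method == "nearest_rank":
        rank = math.ceil(q * n)
        rank = min(max(rank, 1), n)
        return Fraction(sorted_vals[rank - 1])
    if method == "tukey_hinges":
        # median-of-halves; odd n includes the median in both halves
        def med(vals: Sequence[int]) -> Fraction:
            m = len(vals)
            if m % 2:
                return Fraction(vals[m // 2])
            return Fraction(vals[m // 2 - 1] + vals[m // 2], 2)
        if q == Fraction(1, 2):
            return med(sorted_vals)
        half = (n + 1) // 2
        lower = sorted_vals[:half]
        upper = sorted_vals[n - half:]
        return med(lower) if q < Fraction(1, 2) else med(upper)
    raise ValueError(f"unknown quantile method {method!r}")


def _consensus_fractions(
    ratings: Iterable[int], method: str
) -> tuple[Fraction, Fraction, Fraction]:
    vals = sorted(int(r) for r in ratings)
    if not vals:
        raise ValueError("empty rating vector")
    if any(v < 1 or v > 5 for v in vals):
        raise ValueError("ratings must be integers in 1..5")
    return (
        _quantile(vals, Fraction(1, 2), method),
        _quantile(vals, Fraction(1, 4), method),
        _quantile(vals, Fraction(3, 4), method),
    )


def classify_statement(median: float, iqr_width: float,
                       cfg: Optional[DelphiConfig] = None) -> Status:
    """Classify one consensus summary; total over [1,5] x [0,4].

    Exclusion (median < 3.0) takes precedence when both the exclusion and
    wide-IQR conditions hold.
    """
    cfg = cfg or DelphiConfig()
    med = Fraction(median).limit_denominator(1000)
    width = Fraction(iqr_width).limit_denominator(1000)
    if not (1 <= med <= 5):
        raise ValueError(f"median {median} outside [1, 5]")
    if not (0 <= width <= 4):
        raise ValueError(f"IQR width {iqr_width} outside [0, 4]")
    if med < Fraction(cfg.exclude_median_max).limit_denominator(1000):
        return Status.EXCLUDED
    if (med >= Fraction(cfg.include_median_min).limit_denominator(1000)
            and width <= Fraction(cfg.iqr_max).limit_denominator(1000)):
        return Status.INCLUDED
    return Status.QUESTIONABLE


def compute_consensus(ratings: Iterable[int],
                      cfg: Optional[DelphiConfig] = None) -> ConsensusResult:
    """Median/quartile summary and classification of one rating vector."""
    cfg = cfg or DelphiConfig()
    med, q1, q3 = _consensus_fractions(ratings, cfg.quantile_method)
    cls = classify_statement(float(med), float(q3 - q1), cfg)
    return ConsensusResult(
        median=float(med), q1=float(q1), q3=float(q3),
        iqr_width=float(q3 - q1), classification=cls,
    )


# ---------------------------------------------------------------------------
# Rating matrix
# ---------------------------------------------------------------------------

@dataclass
class RatingMatrix:
    """Experts x statements integer Likert ratings with per-cell missingness.

    ``cells[statement_id][expert_id]`` holds an int in 1..5; absent keys are
    missing ratings (e.g. a panelist who dropped out mid-process).
    """

    statements: list[str]
    experts: list[str]
    cells: dict[str, dict[str, int]]

    def vector(self, statement_id: str) -> list[int]:
        """Multiset of non-missing ratings for one statement."""
        if statement_id not in self.cells:
            raise KeyError(f"statement {statement_id!r} not in rating matrix")
        vec = sorted(self.cells[statement_id].values())
        if not vec:
            raise ValueError(f"statement {statement_id!r} has no ratings")
        return vec

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(index=self.statements, columns=self.experts,
                          dtype="object")
        for sid, row in self.cells.items():
            for eid, v in row.items():
                df.loc[sid, eid] = v
        df.index.name = "statement_id"
        return df


def load_rating_matrix(path) -> RatingMatrix:
    """Read a ratings CSV (rows = statements, columns = experts, blank = missing)."""
    df = pd.read_csv(Path(path), index_col=0, dtype=str, keep_default_na=False)
    statements = [str(i) for i in df.index]
    experts = [str(c) for c in df.columns]
    cells: dict[str, dict[str, int]] = {s: {} for s in statements}
    for sid in statements:
        for eid in experts:
            raw = str(df.loc[sid, eid]).strip()
            if raw == "":
                continue
            try:
                v = int(float(raw))
            except ValueError as exc:
                raise ValueError(
                    f"statement {sid!r}, expert {eid!r}: "
                    f"non-integer rating {raw!r}") from exc
            if not 1 <= v <= 5:
                raise ValueError(
                    f"statement {sid!r}, expert {eid!r}: rating {v} "
                    f"outside 1..5")
            cells[sid][eid] = v
    return RatingMatrix(statements, experts, cells)


def write_rating_matrix(rm: RatingMatrix, path) -> None:
    rm.to_frame().to_csv(Path(path), encoding="utf-8")


# ---------------------------------------------------------------------------
# Round orchestration
# ---------------------------------------------------------------------------

def run_round(candidates: Sequence[str], rm: RatingMatrix, round_no: int,
              cfg: Optional[DelphiConfig] = None) -> RoundResult:
    """Partition ``candidates`` by the consensus classification of their ratings.

    Deterministic and order-preserving; raises ``KeyError`` for a candidate
    absent from the matrix.
    """
    cfg = cfg or DelphiConfig()
    included: list[str] = []
    excluded: list[str] = []
    questionable: list[str] = []
    results: dict[str, ConsensusResult] = {}
    for sid in candidates:
        res = compute_consensus(rm.vector(sid), cfg)
        results[sid] = res
        {Status.INCLUDED: included,
         Status.EXCLUDED: excluded,
         Status.QUESTIONABLE: questionable}[res.classification].append(sid)
    return RoundResult(round_no, included, excluded, questionable, results)


def assemble_final_list(
    r1: RoundResult,
    r2: RoundResult,
    metadata: Mapping[str, PIMStatement] | CriteriaSet,
    name: str = "assembled",
) -> CriteriaSet:
    """Merge two round results into a final criteria set.

    Round-2 candidates must be exactly the round-1 questionables plus any
    panel-suggested additions; a statement included in round 1 may not be
    re-rated. The final list is r1.included union r2.included; everything
    else carries EXCLUDED or QUESTIONABLE status. Consensus summaries and
    decided_round are refreshed from the round that settled each statement.
    """
    overlap = set(r1.included) & set(r2.candidates)
    if overlap:
        raise ValueError(
            f"round-2 candidates overlap round-1 inclusions: {sorted(overlap)}")
    missing_q = set(r1.questionable) - set(r2.candidates)
    if missing_q:
        raise ValueError(
            f"round-1 questionable statements missing from round 2: "
            f"{sorted(missing_q)}")

    if isinstance(metadata, CriteriaSet):
        meta = {s.statement_id: s for s in metadata.statements}
    else:
        meta = dict(metadata)

    def build(sid: str, status: Status, round_no: int,
              res: ConsensusResult) -> PIMStatement:
        proto = meta.get(sid)
        if proto is None:
            proto = PIMStatement(
                statement_id=sid, category=Category.INDEPENDENT,
                class_name="", medication_name="", atc_code_printed="",
                atc_code_curated="X", condition_id="",
                median=res.median, iqr_low=res.q1, iqr_high=res.q3,
                status=status, origin=Origin.PRELIMINARY,
                decided_round=round_no)
        stmt = PIMStatement(
            statement_id=sid, category=proto.category,
            class_name=proto.class_name,
            medication_name=proto.medication_name,
            atc_code_printed=proto.atc_code_printed,
            atc_code_curated=proto.atc_code_curated,
            condition_id=proto.condition_id,
            median=res.median, iqr_low=res.q1, iqr_high=res.q3,
            status=status, origin=proto.origin, decided_round=round_no,
            concerns=proto.concerns, alternatives=list(proto.alternatives))
        return stmt

    statements: list[PIMStatement] = []
    for sid in r1.included:
        statements.append(build(sid, Status.INCLUDED, 1, r1.results[sid]))
    for sid in r1.excluded:
        statements.append(build(sid, Status.EXCLUDED, 1, r1.results[sid]))
    for sid in r2.included:
        statements.append(build(sid, Status.INCLUDED, 2, r2.results[sid]))
    for sid in r2.excluded:
        statements.append(build(sid, Status.EXCLUDED, 2, r2.results[sid]))
    for sid in r2.questionable:
        statements.append(build(sid, Status.QUESTIONABLE, 2, r2.results[sid]))
    return CriteriaSet(name, statements)
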