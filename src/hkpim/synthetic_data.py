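"""Synthetic data generators with known ground truth.

Every stage of the pipeline is testable without external data:

* :func:`gen_ratings` inverts the consensus summary — exhaustive enumeration
  of all integer Likert multisets of a given panel size (at most C(n+4, 4),
  i.e. 715 candidates for n = 9) finds a rating vector whose median and
  quartiles equal a target exactly, or proves the target unreachable under
  the chosen quantile method.
* :func:`gen_panel` assembles per-statement vectors into a rating matrix whose
  round outcome is known by construction.
* :func:`gen_round_targets` samples reachable consensus targets landing a
  prescribed number of statements in each class (included / excluded /
  questionable), emulating a Delphi round with chosen outcome counts.
* :func:`gen_patients` plants flaggable medication/condition combinations in
  an exact fraction of a synthetic cohort and returns the planted truth,
  computed by its own naive matcher, for oracle comparison.
* :func:`gen_reference_matrix` draws random reference-list memberships and
  computes the expected candidate selection independently of the selection
  module.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .criteria_model import Category, CriteriaSet, PIMStatement, Status
from .delphi import DelphiConfig, RatingMatrix, _consensus_fractions
from .screening import Flag, PatientRecord
from .selection import BEERS, REFERENCE_LISTS, ReferenceIncidence

__all__ = [
    "ConsensusTarget",
    "CohortSpec",
    "UnreachableTargetError",
    "enumerate_rating_vectors",
    "gen_ratings",
    "gen_panel",
    "gen_round_targets",
    "gen_patients",
    "gen_reference_matrix",
]


class UnreachableTargetError(ValueError):
    """No integer rating multiset of the given size attains the target summary."""


@dataclass
class ConsensusTarget:
    """A (median, Q1, Q3) summary a generated rating vector must reproduce."""

    statement_id: str
    target_median: float
    target_q1: float
    target_q3: float
    n_experts: int

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if not (self.target_q1 <= self.target_median <= self.target_q3):
            raise ValueError(
                f"target {self.statement_id!r}: need q1 <= median <= q3")

    def summary(self) -> tuple[Fraction, Fraction, Fraction]:
        return (Fraction(self.target_median).limit_denominator(1000),
                Fraction(self.target_q1).limit_denominator(1000),
                Fraction(self.target_q3).limit_denominator(1000))


@dataclass
class CohortSpec:
    """Parameters of a synthetic screening cohort.

    ``pim_rate`` is the exact fraction of patients planted with at least one
    flaggable medication/condition combination; the remaining patients receive
    only medications verified not to match any statement.
    """

    n_patients: int
    seed: int
    pim_rate: float = 0.4
    meds_per_patient: tuple[int, int] = (1, 5)  # uniform inclusive range
    condition_prob: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.pim_rate <= 1.0):
            raise ValueError("pim_rate must be in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


# ---------------------------------------------------------------------------
# Rating-vector generation by exhaustive multiset enumeration
# ---------------------------------------------------------------------------

def enumerate_rating_vectors(n: int) -> Iterable[tuple[int, ...]]:
    """All sorted integer multisets of size ``n`` over {1..5}."""
    return itertools.combinations_with_replacement(range(1, 6), n)


def _matching_vectors(
    t: ConsensusTarget, quantile_method: str
) -> list[tuple[int, ...]]:
    want = t.summary()
    out = []
    for vec in enumerate_rating_vectors(t.n_experts):
        if _consensus_fractions(vec, quantile_method) == want:
            out.append(vec)
    return out


def gen_ratings(
    t: ConsensusTarget,
    quantile_method: str = "linear_interpolation",
    seed: int = 0,
) -> list[int]:
    """A rating vector whose consensus summary equals the target exactly.

    Enumeration is exhaustive, so a raised :class:`UnreachableTargetError`
    is a proof that no integer multiset of size ``n_experts`` attains the
    summary under ``quantile_method``. The seed picks among solutions.
    """
    solutions = _matching_vectors(t, quantile_method)
    if not solutions:
        raise UnreachableTargetError(
            f"target {t.statement_id!r} (median={t.target_median}, "
            f"q1={t.target_q1}, q3={t.target_q3}) unreachable with "
            f"{t.n_experts} raters under {quantile_method}")
    rng = random.Random(seed)
    return list(rng.choice(solutions))


def gen_panel(
    targets: Sequence[ConsensusTarget],
    quantile_method: str = "linear_interpolation",
    seed: int = 0,
) -> RatingMatrix:
    """Assemble per-target rating vectors into one rating matrix.

    Statements with fewer raters than the widest panel get missing cells for
    the trailing experts (emulating mid-process dropout). ``run_round`` on the
    result reproduces each target's classification by construction.
    """
    n_experts = max((t.n_experts for t in targets), default=0)
    experts = [f"E{i + 1}" for i in range(n_experts)]
    statements = [t.statement_id for t in targets]
    if len(set(statements)) != len(statements):
        raise ValueError("duplicate statement_id among targets")
    cells: dict[str, dict[str, int]] = {}
    rng = random.Random(seed)
    for t in targets:
        vec = gen_ratings(t, quantile_method, seed=rng.randrange(2**31))
        rng.shuffle(vec)  # ratings are anonymous; order carries no meaning
        cells[t.statement_id] = {experts[i]: v for i, v in enumerate(vec)}
    return RatingMatrix(statements, experts, cells)


def gen_round_targets(
    n_included: int,
    n_excluded: int,
    n_questionable: int,
    n_experts: int,
    seed: int,
    cfg: Optional[DelphiConfig] = None,
    prefix: str = "S",
) -> list[ConsensusTarget]:
    """Sample reachable consensus targets landing the prescribed counts in
    each class. Statement ids are ``{prefix}0001``... in a shuffled class order
    so class membership is not positional."""
    cfg = cfg or DelphiConfig()
    rng = random.Random(seed)

    # classify every attainable summary of this panel size once
    from .delphi import classify_statement
    by_class: dict[Status, list[tuple[Fraction, Fraction, Fraction]]] = {
        Status.INCLUDED: [], Status.EXCLUDED: [], Status.QUESTIONABLE: []}
    seen: set[tuple] = set()
    for vec in enumerate_rating_vectors(n_experts):
        summ = _consensus_fractions(vec, cfg.quantile_method)
        if summ in seen:
            continue
        seen.add(summ)
        med, q1, q3 = summ
        by_class[classify_statement(float(med), float(q3 - q1), cfg)].append(summ)

    wants = ([Status.INCLUDED] * n_included + [Status.EXCLUDED] * n_excluded
             + [Status.QUESTIONABLE] * n_questionable)
    rng.shuffle(wants)
    targets = []
    for i, cls in enumerate(wants):
        pool = by_class[cls]
        if not pool:
            raise UnreachableTargetError(
                f"no attainable {cls.value} summary with {n_experts} raters")
        med, q1, q3 = rng.choice(pool)
        targets.append(ConsensusTarget(
            statement_id=f"{prefix}{i + 1:04d}",
            target_median=float(med), target_q1=float(q1),
            target_q3=float(q3), n_experts=n_experts))
    return targets


# ---------------------------------------------------------------------------
# Patient cohorts with planted ground truth
# ---------------------------------------------------------------------------

def _synthesize_member(code: str) -> str:
    """A plausible substance-level code under a class-level ATC code."""
    if len(code) == 7:
        return code
    base = code
    if len(base) == 1:  # anatomical group -> invent a therapeutic subgroup
        base += "99"
    while len(base) < 5:  # extend to chemical subgroup with placeholder letters
        base += "X"
    return base + "99"


def _naive_match(med: str, s: PIMStatement) -> bool:
    code = s.atc_code_curated
    return med == code or (len(code) < 7 and med.startswith(code))


def gen_patients(
    spec: CohortSpec, cs: CriteriaSet
) -> tuple[list[PatientRecord], list[Flag]]:
    """Synthetic cohort with exactly ``round(n * pim_rate)`` flagged patients.

    Returns the records and the planted ground-truth flags. Truth is computed
    by this module's own naive matcher over the planted medications only;
    filler medications are rejection-sampled against every statement, so the
    screening engine must reproduce the truth exactly (before primary/secondary
    demotion, which only annotates flags).
    """
    included = cs.included()
    if not included:
        raise ValueError("criteria set has no INCLUDED statements")
    n_flagged = round(spec.n_patients * spec.pim_rate)
    if n_flagged > 0 and not included:
        raise ValueError("pim_rate > 0 with no flaggable statements")
    rng = random.Random(spec.seed)

    independent = [s for s in included if s.category is Category.INDEPENDENT]
    cond_specific = [s for s in included
                     if s.category is Category.CONDITION_SPECIFIC]

    # universe of plantable substance codes per statement
    plantable: list[tuple[PIMStatement, str]] = []
    fixture_subst = sorted({s.atc_code_curated for s in included
                            if len(s.atc_code_curated) == 7})
    for s in included:
        code = s.atc_code_curated
        if len(code) == 7:
            plantable.append((s, code))
        else:
            members = [c for c in fixture_subst if c.startswith(code)]
            plantable.append((s, members[0] if members else
                              _synthesize_member(code)))

    all_conditions = sorted({s.condition_id for s in cond_specific})

    def random_filler() -> str:
        # substance code matching no statement at all
        letters = "ABCDGHJLMNPRSV"
        while True:
            code = (rng.choice(letters) + f"{rng.randrange(100):02d}"
                    + rng.choice("ABCDEX") + rng.choice("ABCDEX")
                    + f"{rng.randrange(100):02d}")
            if not any(_naive_match(code, s) for s in cs.statements):
                return code

    flagged_idx = set(rng.sample(range(spec.n_patients), n_flagged))
    records: list[PatientRecord] = []
    truth: list[Flag] = []
    lo, hi = spec.meds_per_patient
    for i in range(spec.n_patients):
        pid = f"P{i + 1:04d}"
        age = rng.randint(65, 95)
        n_meds = rng.randint(lo, hi)
        meds: list[str] = []
        conditions: list[str] = []
        planted: list[str] = []
        if i in flagged_idx:
            stmt, med = rng.choice(plantable)
            planted.append(med)
            if stmt.category is Category.CONDITION_SPECIFIC:
                conditions.append(stmt.condition_id)
        else:
            # conditions alone can never flag: filler meds match nothing
            if all_conditions and rng.random() < spec.condition_prob:
                conditions.append(rng.choice(all_conditions))
        meds.extend(planted)
        while len(meds) < n_meds or (i in flagged_idx and not meds):
            meds.append(random_filler())
        rng.shuffle(meds)
        records.append(PatientRecord(pid, age, meds, sorted(set(conditions))))
        # ground truth: naive scan of the planted medications only
        for med in planted:
            for s in included:
                if not _naive_match(med, s):
                    continue
                if s.category is Category.CONDITION_SPECIFIC \
                        and s.condition_id not in conditions:
                    continue
                truth.append(Flag(
                    patient_id=pid, statement_id=s.statement_id,
                    matched_medication=med,
                    match_level="EXACT" if med == s.atc_code_curated
                    else "CLASS_PREFIX",
                    matched_condition=(s.condition_id
                                       if s.category is
                                       Category.CONDITION_SPECIFIC else ""),
                    category=s.category))
    return records, truth


# ---------------------------------------------------------------------------
# Reference incidence tables with known selections
# ---------------------------------------------------------------------------

def gen_reference_matrix(
    n_entities: int, seed: int
) -> tuple[list[ReferenceIncidence], list[str]]:
    """Random incidence table plus the expected selection, computed here by
    the literal rule (>= 3 lists, or exactly 2 including Beers) independently
    of the selection module."""
    if n_entities < 1:
        raise ValueError("n_entities must be >= 1")
    rng = random.Random(seed)
    lists = sorted(REFERENCE_LISTS)
    rows: list[ReferenceIncidence] = []
    expected: list[str] = []
    for i in range(n_entities):
        k = rng.randint(1, 4)
        members = frozenset(rng.sample(lists, k))
        code = (rng.choice("ACGJMNR") + f"{rng.randrange(100):02d}"
                + rng.choice("ABCDE") + rng.choice("ABCDE")
                + f"{rng.randrange(100):02d}")
        row = ReferenceIncidence(entity=f"entity_{i + 1:03d}", atc_code=code,
                                 memberships=members)
        rows.append(row)
        if len(members) >= 3 or (len(members) == 2 and BEERS in members):
            expected.append(row.entity)
    return rows, expected
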