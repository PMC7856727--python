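"""Preliminary PIM candidate selection.

Candidates are drawn from an incidence table recording, for each medication or
medication class, which of nine published explicit reference criteria list it.
The selection rule: an entity qualifies when it appears in at least two
reference lists, and when it appears in exactly two, one of them must be the
2015 Beers criteria (the de-facto gold standard many national lists derive
from). Selected candidates are then filtered by availability in the local
hospital-authority drug formulary, and class-level candidates are expanded to
their formulary member substances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .criteria_model import atc_level, is_valid_atc

__all__ = [
    "REFERENCE_LISTS",
    "BEERS",
    "ReferenceIncidence",
    "Formulary",
    "select_candidates",
    "filter_by_formulary",
    "expand_class_members",
    "load_incidence_table",
    "load_formulary",
]

logger = logging.getLogger(__name__)

#: The nine published reference criteria the incidence table may cite.
REFERENCE_LISTS = frozenset({
    "McLeod", "Rancourt", "Lindblad", "Laroche", "WinitWatjana",
    "NORGEP", "PRISCUS", "STOPPv2", "Beers2015",
})

BEERS = "Beers2015"


@dataclass
class ReferenceIncidence:
    """One medication/class row of the reference-criteria incidence table."""

    entity: str
    atc_code: str = ""  # optional; empty when only a name is known
    memberships: frozenset[str] = frozenset()
    conditions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.memberships = frozenset(self.memberships)
        unknown = self.memberships - REFERENCE_LISTS
        if unknown:
            raise ValueError(f"entity {self.entity!r}: unknown reference "
                             f"list(s) {sorted(unknown)}")
        if not self.memberships:
            raise ValueError(f"entity {self.entity!r}: empty memberships")

    @property
    def key(self) -> str:
        return self.atc_code if self.atc_code else self.entity.strip().lower()


@dataclass
class Formulary:
    """Available ATC codes plus a class -> member-substance map."""

    codes: set[str]
    class_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, members in self.class_members.items():
            for m in members:
                if not m.startswith(cls):
                    raise ValueError(
                        f"formulary member {m} does not extend class {cls}")


def select_candidates(
    table: Sequence[ReferenceIncidence],
    min_lists: int = 2,
    beers_required_at_min: bool = True,
) -> list[ReferenceIncidence]:
    """Apply the multi-list selection rule; order-preserving.

    With the defaults an entity is selected iff it appears in >= 3 reference
    lists, or in exactly 2 of which one is the Beers criteria. ``min_lists``
    raises the overall membership floor for sensitivity analysis.
    """
    out: list[ReferenceIncidence] = []
    for row in table:
        k = len(row.memberships)
        if k < min_lists:
            continue
        if k == min_lists == 2 and beers_required_at_min \
                and BEERS not in row.memberships:
            continue
        out.append(row)
    return out


def filter_by_formulary(
    selected: Sequence[ReferenceIncidence], f: Formulary
) -> list[ReferenceIncidence]:
    """Retain entities whose ATC code (or any class member) is on formulary."""
    out: list[ReferenceIncidence] = []
    for row in selected:
        if not row.atc_code:
            raise ValueError(f"entity {row.entity!r} lacks an ATC code; "
                             f"cannot check formulary availability")
        code = row.atc_code
        if code in f.codes:
            out.append(row)
            continue
        members = f.class_members.get(code, [])
        if any(m in f.codes for m in members):
            out.append(row)
            continue
        # class code may cover formulary substances even without an explicit map
        if atc_level(code) < 5 and any(c.startswith(code) for c in f.codes):
            out.append(row)
    return out


def expand_class_members(
    entity: ReferenceIncidence, f: Formulary
) -> list[ReferenceIncidence]:
    """Expand a class-level entity into its formulary member substances.

    A substance-level entity is returned unchanged (identity). A class with
    no known members yields an empty list and a logged warning.
    """
    code = entity.atc_code
    if not is_valid_atc(code):
        raise ValueError(f"entity {entity.entity!r}: invalid ATC code {code!r}")
    if atc_level(code) == 5:
        return [entity]
    members = f.class_members.get(code)
    if members is None:
        members = sorted(c for c in f.codes
                         if len(c) == 7 and c.startswith(code))
    if not members:
        logger.warning("class %s (%s) has no formulary members",
                       entity.entity, code)
        return []
    return [
        ReferenceIncidence(
            entity=f"{entity.entity}:{m}",
            atc_code=m,
            memberships=entity.memberships,
            conditions=list(entity.conditions),
        )
        for m in members
    ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_incidence_table(path) -> list[ReferenceIncidence]:
    """Read an incidence CSV: entity, atc_code, one 0/1 column per reference
    list, and pipe-separated ``condition:source`` tokens."""
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    rows: list[ReferenceIncidence] = []
    list_cols = [c for c in df.columns if c in REFERENCE_LISTS]
    unknown = [c for c in df.columns
               if c not in list_cols + ["entity", "atc_code", "conditions"]]
    if unknown:
        raise ValueError(f"unknown incidence columns {unknown}; reference "
                         f"lists must be one of {sorted(REFERENCE_LISTS)}")
    for rec in df.to_dict("records"):
        members = frozenset(c for c in list_cols
                            if str(rec.get(c, "")).strip() in {"1", "True", "true"})
        conds = []
        for tok in str(rec.get("conditions", "")).split("|"):
            tok = tok.strip()
            if tok:
                cid, _, src = tok.partition(":")
                conds.append((cid, src))
        rows.append(ReferenceIncidence(
            entity=rec["entity"], atc_code=rec.get("atc_code", ""),
            memberships=members, conditions=conds))
    return rows


def load_formulary(path) -> Formulary:
    """Read a formulary CSV with columns ``atc_code`` and optional
    ``class_members`` (pipe-separated substance codes)."""
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    codes: set[str] = set()
    class_members: dict[str, list[str]] = {}
    for rec in df.to_dict("records"):
        code = rec["atc_code"].strip()
        if code:
            codes.add(code)
        members = [m for m in str(rec.get("class_members", "")).split("|") if m]
        if members:
            class_members[code] = members
            codes.update(members)
    return Formulary(codes=codes, class_members=class_members)
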