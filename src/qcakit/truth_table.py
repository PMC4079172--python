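"""Truth-table construction, consistency scoring and row classification.

For k selected conditions the truth table enumerates all 2^k fully
specified configurations ("corners").  Each case is assigned to the single
corner it is more in than out of (membership > 0.5 per condition; exactly
0.5 is undecidable and rejected).  Raw consistency of a corner's
configuration is the fuzzy sufficiency score sum(min(x, y)) / sum(x)
computed over *all* cases — partial members contribute, which is what makes
fuzzy consistencies differ from simple member counting.

Rows are classified as:

* remainder      — no assigned cases (consistency undefined);
* contradiction  — assigned cases disagree about the outcome (some above
                   and some below the 0.5 crossover);
* positive       — consistency at or above the cutoff (default 0.75) and
                   enough cases (default frequency cutoff 1);
* negative       — everything else.

A mixed row is flagged as contradictory even when its consistency clears
the cutoff: sufficiency is not claimed for a configuration whose own cases
disagree, and the resolution strategies below decide its fate instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from itertools import product
from pathlib import Path
from typing import Sequence

import pandas as pd

from .data_model import Case, DataTable
from .errors import MembershipAssignmentError, QcaError, UndefinedMetricError
from .metrics import inclusion
from .rounding import fmt3
from .set_algebra import Configuration, Literal, config_membership, format_label

MAX_CONDITIONS = 8

FLAG_ONLY = "flag_only"
RECODE_ZERO = "recode_zero"
VOTE_COUNT = "vote_count"


class OutcomeClass(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    CONTRADICTION = "contradiction"
    REMAINDER = "remainder"


def assign_row(case: Case, conditions: Sequence[str]) -> tuple[int, ...]:
    """Corner a case belongs to: per condition, 1 if membership > 0.5 else 0.

    A membership of exactly 0.5 is precisely neither in nor out and cannot
    be assigned; calibration must be revisited for that case.
    """
    corner = []
    for name in conditions:
        m = case.membership(name)
        if m == 0.5:
            raise MembershipAssignmentError(
                f"case {case.case_id!r}: membership in {name!r} is exactly 0.5 and cannot be "
                "assigned to a truth-table corner; revisit the calibration"
            )
        corner.append(1 if m > 0.5 else 0)
    return tuple(corner)


def corner_configuration(corner: Sequence[int], conditions: Sequence[str]) -> Configuration:
    """The fully specified configuration for a corner (1 = present, 0 = absent)."""
    return Configuration(
        tuple(Literal(name, present=bool(bit)) for name, bit in zip(conditions, corner, strict=True))
    )


def raw_consistency(table: DataTable, config: Configuration, outcome_negated: bool = False) -> float:
    """Fuzzy sufficiency consistency of a configuration for the outcome,
    sum(min(x, y)) / sum(x) over all cases.  Undefined (raises) when no case
    has any membership in the configuration."""
    x = [config_membership(case, config) for case in table.cases]
    y = table.outcome_values(negated=outcome_negated)
    try:
        return inclusion(x, y)
    except UndefinedMetricError as exc:
        raise UndefinedMetricError(
            f"no case has membership in {format_label(config)}; the configuration is a remainder"
        ) from exc


def detect_contradiction(
    row: "TruthTableRow", table: DataTable | None = None, outcome_negated: bool | None = None
) -> tuple[bool, str]:
    """Whether the row's member cases disagree about the (possibly negated)
    analysed outcome: at least one member above and one below 0.5.

    The member outcomes stored on the row are already on the analysed scale,
    so ``table``/``outcome_negated`` are accepted only for interface
    symmetry.
    """
    outcomes = row.member_outcomes
    note = ", ".join(f"{cid}={fmt3(y)}" for cid, y in zip(row.case_ids, outcomes))
    above = any(y > 0.5 for y in outcomes)
    below = any(y < 0.5 for y in outcomes)
    return (above and below), f"member outcomes: {note}" if note else "no member cases"


@dataclass(frozen=True)
class TruthTableRow:
    corner: tuple[int, ...]
    case_ids: tuple[str, ...]
    member_outcomes: tuple[float, ...]  # on the analysed (possibly negated) scale
    raw_consistency: float | None
    outcome_class: OutcomeClass
    note: str = ""

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)


@dataclass(frozen=True)
class TruthTable:
    conditions: tuple[str, ...]
    rows: tuple[TruthTableRow, ...]
    consistency_cutoff: float
    frequency_cutoff: int
    outcome_negated: bool

    def row(self, corner: Sequence[int]) -> TruthTableRow:
        corner = tuple(corner)
        for row in self.rows:
            if row.corner == corner:
                return row
        raise QcaError(f"no truth-table row for corner {corner}")

    def corners_of_class(self, outcome_class: OutcomeClass) -> tuple[tuple[int, ...], ...]:
        return tuple(r.corner for r in self.rows if r.outcome_class is outcome_class)

    @property
    def positive_corners(self):
        return self.corners_of_class(OutcomeClass.POSITIVE)

    @property
    def remainder_corners(self):
        return self.corners_of_class(OutcomeClass.REMAINDER)

    def to_frame(self) -> pd.DataFrame:
        """Display layout: one column per condition, case count, outcome
        class, raw consistency at three decimals (blank for remainders)."""
        records = []
        for row in self.rows:
            rec = dict(zip(self.conditions, row.corner))
            rec["n_cases"] = row.n_cases
            rec["outcome_class"] = row.outcome_class.value
            rec["raw_consistency"] = "" if row.raw_consistency is None else fmt3(row.raw_consistency)
            records.append(rec)
        return pd.DataFrame.from_records(records)


def build_truth_table(
    table: DataTable,
    conditions: Sequence[str] | None = None,
    *,
    consistency_cutoff: float = 0.75,
    frequency_cutoff: int = 1,
    outcome_negated: bool = False,
    max_conditions: int = MAX_CONDITIONS,
) -> TruthTable:
    """Build the 2^k truth table for the selected conditions.

    Rows are sorted by descending raw consistency (ties by descending
    corner), remainders last.  Every case lands in exactly one row, so row
    case counts sum to the number of cases.
    """
    if conditions is None:
        names = list(table.condition_names)
    else:
        names = [table.condition(c).name for c in conditions]
    k = len(names)
    if not 1 <= k <= max_conditions:
        raise QcaError(f"between 1 and {max_conditions} conditions required, got {k}")

    assigned: dict[tuple[int, ...], list[Case]] = {}
    for case in table.cases:
        assigned.setdefault(assign_row(case, names), []).append(case)

    rows = []
    for corner in product((0, 1), repeat=k):
        members = assigned.get(corner, [])
        ids = tuple(c.case_id for c in members)
        outcomes = tuple((1.0 - c.outcome) if outcome_negated else c.outcome for c in members)
        if not members:
            rows.append(
                TruthTableRow(corner, (), (), None, OutcomeClass.REMAINDER, note="no observed cases")
            )
            continue
        consistency = raw_consistency(table, corner_configuration(corner, names), outcome_negated)
        row = TruthTableRow(corner, ids, outcomes, consistency, OutcomeClass.NEGATIVE)
        contradictory, note = detect_contradiction(row)
        if contradictory:
            outcome_class = OutcomeClass.CONTRADICTION
        elif consistency >= consistency_cutoff and len(members) >= frequency_cutoff:
            outcome_class = OutcomeClass.POSITIVE
        else:
            outcome_class = OutcomeClass.NEGATIVE
        rows.append(replace(row, outcome_class=outcome_class, note=note))

    occupied = [r for r in rows if r.outcome_class is not OutcomeClass.REMAINDER]
    remainders = [r for r in rows if r.outcome_class is OutcomeClass.REMAINDER]
    occupied.sort(key=lambda r: (-r.raw_consistency, tuple(-b for b in r.corner)))
    remainders.sort(key=lambda r: r.corner)
    return TruthTable(
        conditions=tuple(names),
        rows=tuple(occupied + remainders),
        consistency_cutoff=consistency_cutoff,
        frequency_cutoff=frequency_cutoff,
        outcome_negated=outcome_negated,
    )


def resolve_contradictions(truth_table: TruthTable, strategy: str = FLAG_ONLY) -> TruthTable:
    """Apply a contradiction-resolution strategy.

    * ``flag_only``   — leave classes as built (contradiction rows stay out
      of minimisation);
    * ``recode_zero`` — recode contradictory rows as negative ("unclear");
    * ``vote_count``  — class by majority of members above vs below the 0.5
      crossover; ties are conservative (negative).
    """
    if strategy not in (FLAG_ONLY, RECODE_ZERO, VOTE_COUNT):
        raise QcaError(f"unknown contradiction strategy {strategy!r}")
    if strategy == FLAG_ONLY:
        return truth_table
    rows = []
    for row in truth_table.rows:
        if row.outcome_class is not OutcomeClass.CONTRADICTION:
            rows.append(row)
            continue
        if strategy == RECODE_ZERO:
            rows.append(replace(row, outcome_class=OutcomeClass.NEGATIVE, note=row.note + " [recoded 0]"))
        else:
            votes_for = sum(1 for y in row.member_outcomes if y > 0.5)
            votes_against = sum(1 for y in row.member_outcomes if y < 0.5)
            winner = OutcomeClass.POSITIVE if votes_for > votes_against else OutcomeClass.NEGATIVE
            rows.append(
                replace(
                    row,
                    outcome_class=winner,
                    note=row.note + f" [vote {votes_for}:{votes_against}]",
                )
            )
    return replace(truth_table, rows=tuple(rows))


@dataclass(frozen=True)
class TruthTableDiagnostics:
    """Spread-of-evidence checks run after building a truth table."""

    n_rows: int
    n_remainders: int
    remainder_fraction: float
    class_counts: dict[str, int]
    has_positive: bool
    has_negative: bool
    max_row_occupancy: int
    limited_diversity: bool
    warnings: tuple[str, ...]


def quality_report(
    truth_table: TruthTable, *, limited_diversity_fraction: float = 0.5
) -> TruthTableDiagnostics:
    """Diagnostics on evidence spread: remainder share, class balance, and a
    limited-diversity warning when too many configurations are unobserved
    (the analysis degenerates into a description of individual studies)."""
    rows = truth_table.rows
    counts: dict[str, int] = {c.value: 0 for c in OutcomeClass}
    for row in rows:
        counts[row.outcome_class.value] += 1
    n_remainders = counts[OutcomeClass.REMAINDER.value]
    fraction = n_remainders / len(rows)
    limited = fraction > limited_diversity_fraction
    warnings = []
    if limited:
        warnings.append(
            f"limited diversity: {n_remainders} of {len(rows)} configurations have no cases"
        )
    n_positive = counts[OutcomeClass.POSITIVE.value]
    if n_positive == 0:
        warnings.append("no configuration passes the consistency cutoff")
    elif n_positive == 1 and len(rows) > 2:
        # with a single condition one passing row is all there can be;
        # beyond that, a lone passing row describes one configuration only
        warnings.append("only one configuration passes the consistency cutoff")
    return TruthTableDiagnostics(
        n_rows=len(rows),
        n_remainders=n_remainders,
        remainder_fraction=fraction,
        class_counts=counts,
        has_positive=bool(n_positive),
        has_negative=bool(counts[OutcomeClass.NEGATIVE.value]),
        max_row_occupancy=max(r.n_cases for r in rows),
        limited_diversity=limited,
        warnings=tuple(warnings),
    )


def write_truth_table(truth_table: TruthTable, path: str | Path, *, delimiter: str = ",") -> None:
    truth_table.to_frame().to_csv(path, sep=delimiter, index=False)
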