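"""Consistency and coverage metrics for configurations and solutions.

Both metrics are fuzzy set-inclusion scores.  For antecedent memberships
x_i and outcome memberships y_i:

* sufficiency consistency of X for Y:  sum_i min(x_i, y_i) / sum_i x_i
* coverage of Y by X:                  sum_i min(x_i, y_i) / sum_i y_i

Coverage of Y by X therefore equals the consistency of Y as an antecedent
for X (duality).  For crisp memberships the scores reduce to the familiar
counting ratios: the fraction of X-members that are Y-members, and the
fraction of Y-members that are X-members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .data_model import DataTable
from .errors import UndefinedMetricError
from .minimise import Solution
from .set_algebra import Expression, expr_membership, format_label


def overlap(x: Sequence[float], y: Sequence[float]) -> float:
    """Sum of pointwise minima (size of the fuzzy intersection)."""
    return sum(min(a, b) for a, b in zip(x, y, strict=True))


def inclusion(antecedent: Sequence[float], outcome: Sequence[float]) -> float:
    """Fuzzy inclusion of the antecedent set in the outcome set:
    sum(min(x, y)) / sum(x).  This is sufficiency consistency; called with
    the roles swapped it is coverage."""
    denom = sum(antecedent)
    if denom == 0:
        raise UndefinedMetricError("antecedent memberships sum to zero")
    return overlap(antecedent, outcome) / denom


def _memberships(table: DataTable, expr: Expression) -> list[float]:
    return [expr_membership(case, expr) for case in table.cases]


def solution_coverage(table: DataTable, expr: Expression, *, outcome_negated: bool = False) -> float:
    """Proportion of the outcome accounted for by the expression:
    sum(min(s, y)) / sum(y)."""
    y = table.outcome_values(negated=outcome_negated)
    if sum(y) == 0:
        raise UndefinedMetricError("outcome memberships sum to zero; coverage undefined")
    return inclusion(y, _memberships(table, expr))


def solution_consistency(table: DataTable, expr: Expression, *, outcome_negated: bool = False) -> float:
    """Proportion of the expression's membership that lies in the outcome:
    sum(min(s, y)) / sum(s)."""
    s = _memberships(table, expr)
    if sum(s) == 0:
        raise UndefinedMetricError("expression memberships sum to zero; consistency undefined")
    return inclusion(s, table.outcome_values(negated=outcome_negated))


@dataclass(frozen=True)
class ComponentMetrics:
    """Per-term metrics: raw coverage counts the term's whole overlap with the
    outcome, unique coverage only the overlap no other term provides."""

    label: str
    raw_coverage: float
    unique_coverage: float
    consistency: float | None


@dataclass(frozen=True)
class SolutionMetrics:
    components: tuple[ComponentMetrics, ...]
    solution_coverage: float
    solution_consistency: float


def component_coverages(
    table: DataTable,
    solution: Solution | Expression,
    *,
    outcome_negated: bool = False,
) -> SolutionMetrics:
    """Raw/unique coverage and consistency per solution term, plus the
    overall solution coverage and consistency.

    Unique coverage of term C is the drop in covered overlap when C is
    removed from the solution; for a single-term solution it equals the raw
    (= solution) coverage.  Raw and unique coverage are reported as separate
    quantities — they coincide only when terms do not overlap on any case.
    """
    expr = solution.expression if isinstance(solution, Solution) else solution
    order = table.condition_names
    y = table.outcome_values(negated=outcome_negated)
    sum_y = sum(y)
    if sum_y == 0:
        raise UndefinedMetricError("outcome memberships sum to zero; coverage undefined")
    s = _memberships(table, expr)
    if sum(s) == 0:
        raise UndefinedMetricError("solution memberships sum to zero; consistency undefined")
    sol_overlap = overlap(s, y)

    components = []
    for term in expr.terms:
        c_vals = [expr_membership(case, Expression((term,))) for case in table.cases]
        term_overlap = overlap(c_vals, y)
        raw = term_overlap / sum_y
        consistency = None if sum(c_vals) == 0 else term_overlap / sum(c_vals)
        rest = [t for t in expr.terms if t is not term]
        if rest:
            s_rest = [expr_membership(case, Expression(tuple(rest))) for case in table.cases]
            unique = (sol_overlap - overlap(s_rest, y)) / sum_y
        else:
            unique = sol_overlap / sum_y
        components.append(
            ComponentMetrics(
                label=format_label(term, order),
                raw_coverage=raw,
                unique_coverage=unique,
                consistency=consistency,
            )
        )
    return SolutionMetrics(
        components=tuple(components),
        solution_coverage=sol_overlap / sum_y,
        solution_consistency=sol_overlap / sum(s),
    )
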