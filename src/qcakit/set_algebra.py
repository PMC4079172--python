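"""Fuzzy Boolean algebra over conditions, and the *, ~, + label notation.

A :class:`Configuration` is a conjunction of condition literals; an
:class:`Expression` is a disjunction of configurations (a DNF).  Fuzzy
semantics are the standard ones: conjunction = minimum, disjunction =
maximum, negation = 1 - m.  For crisp memberships these reduce to ordinary
Boolean evaluation.

Labels follow the field's conventions: ``*`` combines conditions (AND),
``~`` marks non-membership (NOT), and ``+`` joins alternative
configurations (OR), e.g. ``Empowerment*Lay-led*~Design`` or
``Intensity + Quality``.  The empty conjunction is the universal set,
written ``1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .data_model import Case, ConditionDef
from .errors import LabelParseError


@dataclass(frozen=True)
class Literal:
    """One condition, asserted present or absent."""

    condition: str
    present: bool = True


@dataclass(frozen=True)
class Configuration:
    """A conjunction of literals, at most one per condition; empty = universal set."""

    literals: tuple[Literal, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "literals", tuple(self.literals))
        names = [lit.condition.casefold() for lit in self.literals]
        if len(set(names)) != len(names):
            raise LabelParseError(f"a condition appears more than once in {self.literals!r}")


@dataclass(frozen=True)
class Expression:
    """A disjunction of configurations (DNF); at least one term, no duplicates."""

    terms: tuple[Configuration, ...]

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.terms:
            raise LabelParseError("an expression needs at least one term")
        keys = [_term_key(t) for t in self.terms]
        if len(set(keys)) != len(keys):
            raise LabelParseError("duplicate terms in expression")


def _term_key(config: Configuration):
    return frozenset((lit.condition.casefold(), lit.present) for lit in config.literals)


def config_membership(case: Case, config: Configuration) -> float:
    """Membership of a case in a configuration: min over literals
    (1 - m for absent literals); 1.0 for the empty configuration."""
    value = 1.0
    for lit in config.literals:
        m = case.membership(lit.condition)
        value = min(value, m if lit.present else 1.0 - m)
    return value


def expr_membership(case: Case, expr: Expression) -> float:
    """Membership of a case in a DNF: max over its terms."""
    return max(config_membership(case, term) for term in expr.terms)


def _order_index(order: Sequence[str] | None):
    if order is None:
        return lambda lit: 0
    folded = [name.casefold() for name in order]

    def index(lit: Literal) -> int:
        try:
            return folded.index(lit.condition.casefold())
        except ValueError:
            return len(folded)

    return index


def format_label(config: Configuration, order: Sequence[str] | None = None) -> str:
    """Canonical label of a configuration; literals follow the declared
    condition order when one is given.  Empty configuration formats as "1"."""
    if not config.literals:
        return "1"
    literals = sorted(config.literals, key=_order_index(order)) if order else list(config.literals)
    return "*".join(("" if lit.present else "~") + lit.condition for lit in literals)


def format_expression(expr: Expression, order: Sequence[str] | None = None) -> str:
    return " + ".join(format_label(term, order) for term in expr.terms)


def parse_label(text: str, conditions: Sequence[ConditionDef | str]) -> Expression:
    """Parse ``*``/``~``/``+`` notation into an :class:`Expression`.

    Condition names match case-insensitively against ``conditions`` and are
    canonicalised to their declared spelling; whitespace around operators is
    ignored.  A lone ``1`` denotes the universal configuration.
    """
    names = [c.name if isinstance(c, ConditionDef) else str(c) for c in conditions]
    canonical = {n.casefold(): n for n in names}
    if not text or not text.strip():
        raise LabelParseError("empty expression", position=0)

    terms: list[Configuration] = []
    offset = 0
    for chunk in text.split("+"):
        term_pos = offset
        offset += len(chunk) + 1
        stripped = chunk.strip()
        if not stripped:
            raise LabelParseError("empty term in expression", position=term_pos)
        if stripped == "1":
            terms.append(Configuration(()))
            continue
        literals: list[Literal] = []
        seen: set[str] = set()
        lit_pos = term_pos
        for token in chunk.split("*"):
            raw = token
            lit_start = lit_pos
            lit_pos += len(raw) + 1
            token = token.strip()
            if not token:
                raise LabelParseError("empty literal in term", position=lit_start)
            present = True
            if token.startswith("~"):
                present = False
                token = token[1:].strip()
                if not token:
                    raise LabelParseError("'~' with no condition name", position=lit_start)
            key = token.casefold()
            if key not in canonical:
                raise LabelParseError(
                    f"unknown condition {token!r} (declared: {', '.join(names)})", position=lit_start
                )
            if key in seen:
                raise LabelParseError(
                    f"condition {canonical[key]!r} appears more than once in a term", position=lit_start
                )
            seen.add(key)
            literals.append(Literal(canonical[key], present))
        terms.append(Configuration(tuple(literals)))
    return Expression(tuple(terms))
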