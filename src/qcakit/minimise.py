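"""Exact Boolean minimisation (Quine-McCluskey with Petrick cover selection).

The positive rows of a truth table form a set of minterms (fully specified
corners of the Boolean hypercube).  Minimisation merges corners that differ
in a single condition into implicants, keeps the maximal (prime) ones, and
selects a minimum-cost subset covering every minterm.  Remainder rows
(configurations with no observed cases) are excluded under the conservative
policy and treated as don't-cares under the parsimonious policy.

Problem sizes in evidence synthesis are small (a handful of conditions), so
exact minimisation — essential primes followed by Petrick expansion — is
used rather than a heuristic; the cap is 8 conditions (256 corners).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

from .errors import NoSolutionError, QcaError
from .set_algebra import Configuration, Expression, Literal, format_label

CONSERVATIVE = "conservative"
PARSIMONIOUS = "parsimonious"

Corner = tuple[int, ...]
Pattern = tuple[int | None, ...]  # None = condition eliminated ("dash")


@dataclass(frozen=True)
class Implicant:
    """A product term: per-condition 0, 1 or None (eliminated)."""

    pattern: Pattern

    def __post_init__(self):
        object.__setattr__(self, "pattern", tuple(self.pattern))

    def matches(self, corner: Corner) -> bool:
        return all(p is None or p == b for p, b in zip(self.pattern, corner, strict=True))

    @property
    def covers(self) -> frozenset[Corner]:
        """Every corner matching the pattern (the implicant's full cube)."""
        axes = [(0, 1) if p is None else (p,) for p in self.pattern]
        return frozenset(product(*axes))

    @property
    def literal_count(self) -> int:
        return sum(1 for p in self.pattern if p is not None)

    def to_configuration(self, names: Sequence[str]) -> Configuration:
        literals = tuple(
            Literal(name, present=bool(bit))
            for name, bit in zip(names, self.pattern, strict=True)
            if bit is not None
        )
        return Configuration(literals)


def _merge(a: Pattern, b: Pattern) -> Pattern | None:
    """Merge two patterns differing in exactly one fixed position."""
    diff = -1
    for i, (x, y) in enumerate(zip(a, b)):
        if x == y:
            continue
        if x is None or y is None or diff >= 0:
            return None
        diff = i
    if diff < 0:
        return None
    return a[:diff] + (None,) + a[diff + 1 :]


def _pattern_sort_key(pattern: Pattern):
    return tuple(2 if p is None else p for p in pattern)


def prime_implicants(minterms: Iterable[Corner], dont_cares: Iterable[Corner] = ()) -> set[Implicant]:
    """All maximal implicants covering only minterms and don't-cares."""
    current: set[Pattern] = {tuple(m) for m in minterms} | {tuple(d) for d in dont_cares}
    if not current:
        raise NoSolutionError("no minterms to minimise")
    primes: set[Pattern] = set()
    while current:
        merged: set[Pattern] = set()
        used: set[Pattern] = set()
        ordered = sorted(current, key=_pattern_sort_key)
        for a, b in combinations(ordered, 2):
            m = _merge(a, b)
            if m is not None:
                merged.add(m)
                used.add(a)
                used.add(b)
        primes |= current - used
        current = merged
    return {Implicant(p) for p in primes}


def _petrick(cover_sets: list[frozenset[Implicant]]) -> set[frozenset[Implicant]]:
    """Expand a product of sums of primes into minimal sum terms (with absorption)."""
    products: set[frozenset[Implicant]] = {frozenset()}
    for options in cover_sets:
        expanded = {p | {q} for p in products for q in options}
        # absorption: drop any product that is a strict superset of another
        minimal = {p for p in expanded if not any(other < p for other in expanded)}
        products = minimal
    return products


def select_cover(
    primes: Iterable[Implicant],
    minterms: Iterable[Corner],
    *,
    tiebreak_key=None,
) -> tuple[Implicant, ...]:
    """Minimum cover of the minterms: essential primes first, the rest by
    exact Petrick expansion minimising (term count, total literal count),
    deterministic ties broken by ``tiebreak_key`` (default: pattern order)."""
    primes = set(primes)
    minterms = {tuple(m) for m in minterms}
    key = tiebreak_key or (lambda imp: _pattern_sort_key(imp.pattern))

    covering: dict[Corner, set[Implicant]] = {}
    for m in minterms:
        covering[m] = {p for p in primes if p.matches(m)}
        if not covering[m]:
            raise QcaError(f"internal error: minterm {m} not covered by any prime implicant")

    essential = {next(iter(opts)) for m, opts in covering.items() if len(opts) == 1}
    covered = set().union(*(p.covers for p in essential)) if essential else set()
    remaining = [m for m in minterms if m not in covered]

    if remaining:
        products = _petrick([frozenset(covering[m]) for m in remaining])
        best = min(
            products,
            key=lambda prod: (
                len(prod),
                sum(p.literal_count for p in prod),
                tuple(sorted(key(p) for p in prod)),
            ),
        )
        chosen = essential | set(best)
    else:
        chosen = essential
    return tuple(sorted(chosen, key=key))


@dataclass(frozen=True)
class Solution:
    """A minimised disjunction of implicants with its provenance."""

    expression: Expression
    policy: str
    minterms: frozenset[Corner]
    dont_cares: frozenset[Corner]


def minimise(
    positive_rows: Iterable[Corner],
    remainder_rows: Iterable[Corner] = (),
    policy: str = CONSERVATIVE,
    conditions: Sequence[str] | None = None,
) -> Solution:
    """Minimal DNF over the positive corners.

    Conservative: remainders excluded (the expression is true exactly on the
    positive set).  Parsimonious: remainders enter as don't-cares (the
    expression is true on all positives and false on all other observed
    corners, remainders free).
    """
    if policy not in (CONSERVATIVE, PARSIMONIOUS):
        raise QcaError(f"unknown minimisation policy {policy!r}")
    positives = {tuple(m) for m in positive_rows}
    remainders = {tuple(m) for m in remainder_rows}
    if not positives:
        raise NoSolutionError("no configuration passed the consistency cutoff")
    if positives & remainders:
        raise QcaError("positive and remainder corner sets overlap")
    k = len(next(iter(positives)))
    if any(len(m) != k for m in positives | remainders):
        raise QcaError("corners have inconsistent arity")
    names = list(conditions) if conditions is not None else [f"c{i + 1}" for i in range(k)]
    if len(names) != k:
        raise QcaError(f"{k} conditions expected, got {len(names)} names")

    dont_cares = remainders if policy == PARSIMONIOUS else set()
    primes = prime_implicants(positives, dont_cares)
    label_key = lambda imp: format_label(imp.to_configuration(names), names)
    cover = select_cover(primes, positives, tiebreak_key=label_key)
    expr = Expression(tuple(imp.to_configuration(names) for imp in cover))
    return Solution(
        expression=expr,
        policy=policy,
        minterms=frozenset(positives),
        dont_cares=frozenset(dont_cares),
    )
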