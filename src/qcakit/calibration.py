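"""Calibration of raw effect sizes into fuzzy outcome memberships.

Effect sizes arrive as odds ratios; calibration maps the logged odds ratio
onto a small ordered set of membership levels anchored at full membership
(1), "more in than out" (0.666), "more out than in" (0.333) and full
non-membership (0), with 0.5 the qualitative crossover.  The default scheme
uses natural-log thresholds 0.7 / 0.4 / 0:

* logged OR >  0.7         -> 1.000  (full member of "highly effective")
* 0.4 < logged OR <= 0.7   -> 0.666
* 0   < logged OR <= 0.4   -> 0.333
* logged OR <= 0           -> 0.000

Boundary semantics follow the interval rules above: a logged OR exactly at
an upper threshold belongs to the lower level (log OR = 0.7 -> 0.666).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DataValidationError, SchemaError

NATURAL = "natural"
BASE10 = "base10"


@dataclass(frozen=True)
class CalibrationScheme:
    """Interval calibration of a logged effect size onto membership levels.

    ``thresholds`` are strictly decreasing breakpoints on the logged-effect
    scale; ``levels`` are the strictly decreasing memberships assigned above
    each threshold interval (one more level than thresholds).
    """

    log_base: str = NATURAL
    thresholds: tuple[float, ...] = (0.7, 0.4, 0.0)
    levels: tuple[float, ...] = (1.0, 0.666, 0.333, 0.0)

    def __post_init__(self):
        if self.log_base not in (NATURAL, BASE10):
            raise SchemaError(f"log_base must be 'natural' or 'base10', got {self.log_base!r}")
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        if len(self.levels) != len(self.thresholds) + 1:
            raise SchemaError("need exactly one more level than thresholds")
        if any(a <= b for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise SchemaError("thresholds must be strictly decreasing")
        if any(a <= b for a, b in zip(self.levels, self.levels[1:])):
            raise SchemaError("levels must be strictly decreasing")
        if any(not 0.0 <= v <= 1.0 for v in self.levels):
            raise SchemaError("levels must lie in [0, 1]")

    def log(self, raw_or: float) -> float:
        return math.log(raw_or) if self.log_base == NATURAL else math.log10(raw_or)


DEFAULT_SCHEME = CalibrationScheme()


def calibrate_effect(raw_or: float, scheme: CalibrationScheme = DEFAULT_SCHEME) -> float:
    """Fuzzy outcome membership for a raw odds ratio.

    A step function of the logged odds ratio, monotone non-decreasing in
    ``raw_or``: the returned level is ``levels[k]`` where ``k`` counts the
    thresholds at or above the logged value.
    """
    if not raw_or > 0:
        raise DataValidationError(f"odds ratios are positive; got {raw_or}")
    logged = scheme.log(raw_or)
    k = sum(1 for t in scheme.thresholds if logged <= t)
    return scheme.levels[k]


def negate(membership: float) -> float:
    """Standard fuzzy complement 1 - m (involution, fixes the 0.5 crossover)."""
    if not 0.0 <= membership <= 1.0:
        raise DataValidationError(f"membership {membership} outside [0, 1]")
    return 1.0 - membership
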