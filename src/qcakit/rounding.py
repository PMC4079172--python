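"""Display rounding helpers.

Memberships, consistencies and coverages are kept at full float precision
internally; reports round half-up to three decimals, the convention used for
fuzzy membership levels such as 0.666 and 0.333.
"""

from decimal import ROUND_HALF_UP, Decimal


def round3(x: float) -> float:
    """Round half-up to three decimals (display convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def fmt3(x: float) -> str:
    """Format with exactly three fractional digits, half-up."""
    return str(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))
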