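"""Decimal rounding primitives shared across the package.

All published numbers in this package go through one of these helpers so the
reporting conventions (half-up integers, one-decimal truncation, quarter-unit
exchange counts) are applied consistently and are immune to binary-float
artifacts such as ``2.675`` rounding down.
"""

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "truncate", "round_quarter_up"]

# Inputs are first snapped to 9 decimals so that values that are mathematically
# exact decimals (e.g. 59.4 computed as 100*29.7/50) do not truncate one step
# too low because of float representation error.
_SNAP = 9


def _as_decimal(x: float) -> Decimal:
    return Decimal(repr(round(float(x), _SNAP)))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with ties away from zero going up."""
    q = Decimal(1).scaleb(-ndigits)
    return float(_as_decimal(x).quantize(q, rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 1) -> float:
    """Truncate toward zero at ``ndigits`` decimals (7.19 -> 7.1, -7.19 -> -7.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(_as_decimal(x).quantize(q, rounding=ROUND_DOWN))


def round_quarter_up(x: float) -> float:
    """Round to the nearest multiple of 0.25, ties rounding up (1.125 -> 1.25)."""
    quarters = (_as_decimal(x) * 4).quantize(Decimal(1), rounding=ROUND_HALF_UP)
    return float(quarters) / 4.0
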