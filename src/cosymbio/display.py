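"""Percent display conventions.

Different report tables in this package print percentages with different
conventions (see docs/methods.md for the rationale); all of them are computed
here with exact rational arithmetic so display never depends on binary
floating point.

* :func:`floor_percent` — whole percent, truncated toward zero.  A prevalence
  report never claims a higher whole-percent than was attained (123/127 is
  shown as 96%, not 97%).
* :func:`percent_half_up` — round half-up at a chosen number of decimals.
* :func:`percent_one_decimal_capped` — one decimal, half-up, but rounding is
  never allowed to carry into the units digit (350/361 = 96.95% is shown as
  96.9%, not 97.0%), keeping the integer part a floor.
"""

from __future__ import annotations

from fractions import Fraction

from .errors import UsageError


def _check(numerator: int, denominator: int) -> None:
    if denominator <= 0:
        raise UsageError("percent denominator must be positive")
    if numerator < 0:
        raise UsageError("percent numerator must be non-negative")


def floor_percent(numerator: int, denominator: int) -> int:
    """Whole-percent display, truncated toward zero."""
    _check(numerator, denominator)
    return (100 * numerator) // denominator


def percent_half_up(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percent rounded half-up to ``decimals`` decimal places."""
    _check(numerator, denominator)
    scale = 10**decimals
    p = Fraction(100 * numerator, denominator) * scale
    # round half up on the exact rational value
    units = (2 * p.numerator + p.denominator) // (2 * p.denominator)
    return units / scale if decimals else float(units)


def percent_one_decimal_capped(numerator: int, denominator: int) -> float:
    """One-decimal percent, half-up, never carrying into the units digit."""
    _check(numerator, denominator)
    p = Fraction(100 * numerator, denominator)
    tenths = (2 * (p * 10).numerator + (p * 10).denominator) // (2 * (p * 10).denominator)
    floor_units = p.numerator // p.denominator
    cap = 10 * floor_units + 9
    if tenths > cap and Fraction(tenths, 10) != p:
        tenths = cap
    return tenths / 10
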