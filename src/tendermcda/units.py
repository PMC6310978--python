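"""Percent parsing and display formatting.

User files mix notations for the same quantity ("40%", "40", "0.40"); everything
is normalized to a fraction on input. Display rounding is half-up to one decimal
percent, so stored full-precision weights print the way decision reports expect
(e.g. 0.187897... -> "18.8%").
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def parse_percent(value: str | float | int) -> float:
    """Normalize a percent-or-fraction notation to a fraction.

    Rule: a bare number greater than 1 is a percent ("40" -> 0.40); a number
    with a trailing ``%`` is always a percent; anything in [0, 1] is already a
    fraction. Values above 100% are allowed (price cut-offs go up to +500%).
    """
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            return float(text[:-1].strip()) / 100.0
        value = float(text)
    value = float(value)
    return value / 100.0 if value > 1.0 else value


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Render a fraction as a percent string, rounding half-up.

    >>> format_percent(0.1878971255673222)
    '18.8%'
    """
    quantum = Decimal(1).scaleb(-decimals)
    pct = (Decimal(repr(float(fraction))) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{pct}%"


def percent_value(fraction: float, decimals: int = 1) -> float:
    """The numeric percent after half-up display rounding (18.8 for 0.18789...)."""
    return float(format_percent(fraction, decimals).rstrip("%"))
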