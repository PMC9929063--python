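"""Small shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, the convention of clinical score tables.

    Plain ``round`` uses banker's rounding (16.5 -> 16), which does not
    reproduce published point tables (16.5 points print as 17).
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * numerator / denominator, decimals)
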