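"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero, matching printed-report conventions.

    Python's builtin round() is banker's rounding; population reports in
    the forensic literature round 0.5 up (7.45 -> 7.5 at one decimal).
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt(x: float, decimals: int = 3) -> str:
    return f"{round_half_up(x, decimals):.{decimals}f}"
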