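"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed summary tables expect.

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    how percentage tables are conventionally printed (e.g. 12.375 -> 12.38).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
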