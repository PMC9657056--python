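"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as engineering tables print values.

    Python's built-in ``round`` uses banker's rounding, which turns the
    exact tie 1.125 into 1.12; factor-of-safety tables conventionally
    print 1.13.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
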