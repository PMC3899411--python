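"""Shared numeric helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half away from zero to ``ndigits`` decimals.

    Published mortality tables round 0.5 up, which differs from Python's
    banker's rounding (``round(2.5) == 2``).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
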