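"""Small shared helpers."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Printed tables in clinical papers are normally formatted half-up, while
    Python's built-in round() is half-even; golden comparisons against
    printed values therefore go through this helper.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
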