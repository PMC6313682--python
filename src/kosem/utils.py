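"""Small shared helpers."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), as report tables expect;
    Python's builtin round is banker's rounding."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))
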