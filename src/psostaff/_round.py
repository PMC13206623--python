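"""Half-up rounding on decimal arithmetic.

Python's built-in ``round`` is banker's rounding; staffing tables are
conventionally rounded half-up (2251.53 -> 2252, 3.345 -> 3.35 at two
decimals).  Doing the quantisation in :mod:`decimal` also avoids binary
float artefacts on exact halves such as 10.70 x 1175 = 12572.50.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def to_decimal(x: float | int | str | Decimal) -> Decimal:
    if isinstance(x, Decimal):
        return x
    if isinstance(x, int):
        return Decimal(x)
    return Decimal(str(x))


def round_half_up(x: float | int | Decimal, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimal places."""
    q = Decimal(1).scaleb(-ndigits)
    return float(to_decimal(x).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up_int(x: float | int | Decimal) -> int:
    """Round half-up to the nearest integer."""
    return int(to_decimal(x).quantize(Decimal(1), rounding=ROUND_HALF_UP))
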