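"""Half-away-from-zero rounding on decimal representations.

Python's built-in round() is banker's rounding on binary floats; published
valuation tables round ties away from zero (e.g. -0.0058 at 2 dp prints as
-0.01), so reported quantities go through Decimal with ROUND_HALF_UP.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, decimals: int = 2) -> float:
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    # repr() keeps the shortest decimal string that round-trips the float,
    # which is the printed value the rounding rule is meant to act on.
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
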