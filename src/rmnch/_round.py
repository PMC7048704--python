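"""Half-up decimal rounding for table parity.

Python's builtin ``round`` uses banker's rounding; published tables round
half-way cases up, so display values go through this helper.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimal places, halves away from zero."""
    if x != x:  # NaN passes through
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))
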