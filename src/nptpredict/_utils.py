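"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), as clinical tables do.

    Python's builtin ``round`` is banker's rounding; diagnostic-accuracy
    tables conventionally round 0.5 up, so we go through Decimal.
    NaN passes through unchanged.
    """
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def norm_sf(z: float) -> float:
    """Upper-tail probability of the standard normal."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def chi2_sf_1df(x: float) -> float:
    """Upper-tail probability of chi-square with 1 df (via the normal)."""
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return math.erfc(math.sqrt(x / 2.0))
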