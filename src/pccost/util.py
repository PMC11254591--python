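"""Shared numeric helpers: reporting rounding rules and discount factors.

Monetary values are carried at full float precision internally; reported
aggregates are truncated to whole euros, percentages are rounded to one
decimal, half away from zero.
"""
from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

# Absorbs float representation error (e.g. 358238.999999997) before flooring;
# far below the 1-euro reporting resolution.
_EURO_EPS = 1e-6


def truncate_euro(x: float) -> float:
    """Truncate a nonnegative monetary amount to whole euros."""
    return float(math.floor(x + _EURO_EPS))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (reporting convention for percents)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def discount_factors(horizon_years: int, rate: float) -> np.ndarray:
    """Per-year present-value factors; year 1 is undiscounted."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return np.power(1.0 + rate, -np.arange(horizon_years, dtype=float))
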