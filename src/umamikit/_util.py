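"""Shared helpers: unit normalization, reporting-precision rounding, logging."""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

log = logging.getLogger("umamikit")

#: multiplicative factors into the canonical unit, mg per 100 g
_UNIT_FACTORS = {
    "mg/100g": 1.0,
    "mg per 100 g": 1.0,
    "mg/100 g": 1.0,
    "ug/g": 0.1,
    "µg/g": 0.1,
    "μg/g": 0.1,
    "g/100g": 1000.0,
    "g/100 g": 1000.0,
}


def to_mg_per_100g(value: float, unit: str) -> float:
    """Convert a concentration to the canonical mg per 100 g."""
    key = unit.strip().lower().replace(" ", "").replace("μ", "u").replace("µ", "u")
    key = {"mg/100g": "mg/100g", "ug/g": "ug/g", "g/100g": "g/100g"}.get(key)
    if key is None:
        raise ValueError(f"unknown concentration unit: {unit!r}")
    return value * _UNIT_FACTORS[key]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for reported tables.

    Python's built-in round() is banker's rounding; reported values such as
    taste-activity ratios are conventionally rounded half-up at 2 decimals.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def configure_logging(quiet: bool = False) -> None:
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.ERROR if quiet else logging.INFO)
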