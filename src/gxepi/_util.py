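"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


class GxepiError(Exception):
    """Base class for package errors."""


class ConfigError(GxepiError):
    """Invalid configuration value or structure."""


class DomainError(GxepiError):
    """Input outside the mathematical domain of an operation."""


class EstimationError(GxepiError):
    """A model could not be estimated from the given data."""


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention used in printed tables.

    Python's built-in ``round`` is banker's rounding; rendered percentages
    and odds ratios use half-up instead (1.005 -> 1.01, 11.45 -> 11.5).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
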