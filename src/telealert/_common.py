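"""Shared helpers: rounding convention, slot labels, exception hierarchy."""

from __future__ import annotations

import math

#: Labels of the four scheduled measurement slots on a measurement day,
#: in within-day order (two morning, two evening readings).
SLOT_LABELS: tuple[str, ...] = ("morning-1", "morning-2", "evening-1", "evening-2")

SLOT_ORDER: dict[str, int] = {s: i for i, s in enumerate(SLOT_LABELS)}


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero-half upward.

    All reported integers (percentages, minutes) use this single convention;
    chained rounding is never applied.
    """
    return math.floor(x + 0.5)


def round_half_up_2dp(x: float) -> float:
    """Round to two decimals, ties upward (used for carried proportions)."""
    return math.floor(x * 100 + 0.5) / 100


def pct(part: float, whole: float) -> int | None:
    """Rounded percentage of ``part`` in ``whole``; None when undefined."""
    if whole == 0:
        return None
    return round_half_up(100.0 * part / whole)


class TelealertError(Exception):
    """Base class for package errors."""


class ConfigurationError(TelealertError):
    """Invalid configuration value; carries the offending field name."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataError(TelealertError):
    """Malformed or inconsistent input data."""


class ContractViolation(TelealertError):
    """An operation precondition was violated by the caller."""
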