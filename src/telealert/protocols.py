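"""Hypertension monitoring protocols (measurement algorithms) and switching.

A home blood-pressure telemonitoring program assigns each user one of an
ordered set of *monitoring protocols*: four acute algorithms with strict
targets and frequent measurement weeks, used while blood pressure is being
brought under control, and one chronic algorithm (140/90 mmHg, one
measurement week per month) for stable users.  During a measurement week the
user measures twice in the morning and twice in the evening.  When the
week's readings meet the protocol target, the platform automatically steps
the user down one rung toward the chronic algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Literal, Optional, Sequence

import numpy as np

from ._common import SLOT_LABELS, ConfigurationError

#: Days in one measurement week.
MEASUREMENT_WEEK_DAYS = 7

WeekRule = Literal["mean", "all", "majority"]
SwitchAction = Literal["step_down", "stay", "step_up"]


@dataclass(frozen=True)
class MonitoringProtocol:
    """One rung of the protocol ladder.

    Parameters
    ----------
    protocol_id:
        Short label, e.g. ``"acute-4"``.
    level:
        Integer rank: 0 is the chronic algorithm, 1..4 are acute with 4 the
        most acute.
    sbp_target, dbp_target:
        Target thresholds in mmHg.  A reading is *on target* when it is
        strictly below both (targets are exclusive upper bounds).
    week_interval_days:
        Days between the starts of consecutive measurement weeks.  Each
        measurement week occupies the first 7 days of the interval.
    measurements_per_day:
        Scheduled readings per measurement day (default 4: two morning and
        two evening slots).
    """

    protocol_id: str
    level: int
    sbp_target: float
    dbp_target: float
    week_interval_days: int
    measurements_per_day: int = 4

    def __post_init__(self) -> None:
        if self.sbp_target <= 0 or self.dbp_target <= 0:
            raise ConfigurationError("sbp_target/dbp_target", "targets must be positive")
        if self.measurements_per_day < 1:
            raise ConfigurationError("measurements_per_day", "must be >= 1")
        if self.week_interval_days < MEASUREMENT_WEEK_DAYS:
            raise ConfigurationError(
                "week_interval_days", "must be at least one measurement week (7 days)"
            )

    def on_target(self, sbp: float, dbp: float) -> bool:
        """True when a reading is strictly below both targets."""
        return sbp < self.sbp_target and dbp < self.dbp_target


@dataclass(frozen=True)
class ProtocolLadder:
    """Ordered set of protocols, most acute first (level descending)."""

    protocols: tuple[MonitoringProtocol, ...]

    def __post_init__(self) -> None:
        levels = [p.level for p in self.protocols]
        if levels != sorted(levels, reverse=True) or len(set(levels)) != len(levels):
            raise ConfigurationError("protocols", "must be ordered by level, descending, unique")
        if levels and levels[-1] != 0:
            raise ConfigurationError("protocols", "ladder must end at chronic level 0")
        for hi, lo in zip(self.protocols, self.protocols[1:]):
            if not (hi.sbp_target > lo.sbp_target and hi.dbp_target > lo.dbp_target):
                raise ConfigurationError(
                    "protocols", "targets must strictly decrease toward chronic"
                )
            if hi.week_interval_days > lo.week_interval_days:
                raise ConfigurationError(
                    "protocols", "week interval must be non-decreasing toward chronic"
                )

    def by_level(self, level: int) -> MonitoringProtocol:
        for p in self.protocols:
            if p.level == level:
                return p
        raise KeyError(f"no protocol at level {level}")

    @property
    def levels(self) -> list[int]:
        return [p.level for p in self.protocols]

    @property
    def chronic(self) -> MonitoringProtocol:
        return self.protocols[-1]

    @property
    def most_acute(self) -> MonitoringProtocol:
        return self.protocols[0]

    def to_records(self) -> list[dict]:
        """Serializable form (list of plain dicts, ladder order)."""
        return [
            {
                "id": p.protocol_id,
                "level": p.level,
                "sbp_target": float(p.sbp_target),
                "dbp_target": float(p.dbp_target),
                "week_interval_days": p.week_interval_days,
                "measurements_per_day": p.measurements_per_day,
            }
            for p in self.protocols
        ]

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "ProtocolLadder":
        protos = tuple(
            MonitoringProtocol(
                protocol_id=str(r["id"]),
                level=int(r["level"]),
                sbp_target=float(r["sbp_target"]),
                dbp_target=float(r["dbp_target"]),
                week_interval_days=int(r["week_interval_days"]),
                measurements_per_day=int(r.get("measurements_per_day", 4)),
            )
            for r in sorted(records, key=lambda r: -int(r["level"]))
        )
        return cls(protos)


# Default ladder: acute targets run 180/110 down to 150/95, chronic 140/90.
# The two most acute rungs use weekly measurement weeks, the two milder
# acute rungs biweekly, and the chronic rung one week per 28 days.
_DEFAULT_LADDER_SPEC = [
    ("acute-4", 4, 180, 110, 7),
    ("acute-3", 3, 170, 105, 7),
    ("acute-2", 2, 160, 100, 14),
    ("acute-1", 1, 150, 95, 14),
    ("chronic", 0, 140, 90, 28),
]


def build_default_ladder() -> ProtocolLadder:
    """Build the default 5-rung ladder (4 acute + 1 chronic)."""
    return ProtocolLadder(
        tuple(
            MonitoringProtocol(pid, level, sbp, dbp, interval)
            for pid, level, sbp, dbp, interval in _DEFAULT_LADDER_SPEC
        )
    )


def schedule_slots(
    protocol: MonitoringProtocol,
    enrollment_date: date,
    horizon_days: int,
) -> list[tuple[date, str]]:
    """Scheduled measurement slots over ``horizon_days`` from enrollment.

    Measurement weeks occupy the first 7 days of each
    ``week_interval_days``-long block counted from the enrollment date; each
    measurement day carries ``measurements_per_day`` slots.  Deterministic
    and user-agnostic: returns (date, slot-label) pairs in chronological,
    within-day order.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    labels = SLOT_LABELS[: protocol.measurements_per_day]
    out: list[tuple[date, str]] = []
    for offset in range(horizon_days):
        if offset % protocol.week_interval_days < MEASUREMENT_WEEK_DAYS:
            d = enrollment_date + timedelta(days=offset)
            out.extend((d, slot) for slot in labels)
    return out


@dataclass(frozen=True)
class WeekOutcome:
    """Result of evaluating one measurement week against its protocol.

    ``on_target`` is None when the week is indeterminate (too few taken
    readings), in which case no switch happens and the week is left for
    inactivity handling.
    """

    on_target: Optional[bool]
    action: SwitchAction
    new_level: int


def evaluate_week(
    sbp: Sequence[float],
    dbp: Sequence[float],
    protocol: MonitoringProtocol,
    *,
    floor_level: int = 0,
    ceiling_level: int = 4,
    rule: WeekRule = "mean",
    allow_escalation: bool = False,
    min_readings: int = 2,
) -> WeekOutcome:
    """Evaluate one user's taken readings of one measurement week.

    Under the default ``"mean"`` rule the week is on target when the mean
    SBP and mean DBP are both strictly below the protocol targets; ``"all"``
    requires every reading on target, ``"majority"`` more than half.  An
    on-target week at a level above ``floor_level`` steps down one level; an
    off-target week stays unless ``allow_escalation`` is set, in which case
    it steps up one level toward ``ceiling_level``.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    if sbp.shape != dbp.shape:
        raise ValueError("sbp and dbp must have equal length")
    if len(sbp) < min_readings:
        return WeekOutcome(None, "stay", protocol.level)

    if rule == "mean":
        on = protocol.on_target(float(sbp.mean()), float(dbp.mean()))
    elif rule == "all":
        on = bool(np.all((sbp < protocol.sbp_target) & (dbp < protocol.dbp_target)))
    elif rule == "majority":
        hits = (sbp < protocol.sbp_target) & (dbp < protocol.dbp_target)
        on = bool(hits.mean() > 0.5)
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown week rule {rule!r}")

    if on and protocol.level > floor_level:
        return WeekOutcome(True, "step_down", protocol.level - 1)
    if not on and allow_escalation and protocol.level < ceiling_level:
        return WeekOutcome(False, "step_up", protocol.level + 1)
    return WeekOutcome(on, "stay", protocol.level)
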