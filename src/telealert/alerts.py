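"""Rule-based alert engine: measurements + thresholds -> typed, routed alerts.

The platform raises three families of alerts:

* **simple** — a single reading crosses a one-off bound (very high/low
  systolic or diastolic BP, or heart rate).  High bounds are inclusive
  (``>=``), low bounds inclusive (``<=``).
* **complex** — a *series* of readings is off target for the user's current
  protocol: ``complex_off_target`` fires once per run of at least ``k``
  consecutive taken off-target readings; ``complex_on_target_switch`` fires
  at the end of an on-target measurement week (the event that drives
  automatic protocol de-escalation and on-target feedback).
* **missed** — ``overdue`` for every missed scheduled slot, ``inactive``
  for a window of at least ``x`` measurement-week days with no readings.

Each alert is routed ``auto`` (handled by the platform) or ``manual``
(reviewed by an e-nurse) according to a total routing policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._common import SLOT_ORDER, ConfigurationError, ContractViolation
from .cohort import Measurement
from .protocols import MonitoringProtocol, ProtocolLadder, build_default_ladder, evaluate_week

ALERT_TYPES = (
    "simple_sbp_high",
    "simple_sbp_low",
    "simple_dbp_high",
    "simple_dbp_low",
    "simple_hr_high",
    "simple_hr_low",
    "complex_off_target",
    "complex_on_target_switch",
    "overdue",
    "inactive",
)

SIMPLE_TYPES = ALERT_TYPES[:6]

#: vital column and bound direction per simple alert type
SIMPLE_RULES: dict[str, tuple[str, str, str]] = {
    "simple_sbp_high": ("sbp", "high", "simple_sbp_high"),
    "simple_sbp_low": ("sbp", "low", "simple_sbp_low"),
    "simple_dbp_high": ("dbp", "high", "simple_dbp_high"),
    "simple_dbp_low": ("dbp", "low", "simple_dbp_low"),
    "simple_hr_high": ("hr", "high", "simple_hr_high"),
    "simple_hr_low": ("hr", "low", "simple_hr_low"),
}

ALERT_COLUMNS = [
    "alert_id",
    "user_id",
    "trigger_date",
    "alert_type",
    "routing",
    "source_measurement_ids",
    "excess",
]

#: Default routing: the platform auto-processes single overdue alerts and
#: on-target (protocol switch) alerts; everything needing review is manual.
DEFAULT_ROUTING: dict[str, str] = {
    "simple_sbp_high": "manual",
    "simple_sbp_low": "manual",
    "simple_dbp_high": "manual",
    "simple_dbp_low": "manual",
    "simple_hr_high": "manual",
    "simple_hr_low": "manual",
    "complex_off_target": "manual",
    "complex_on_target_switch": "auto",
    "overdue": "auto",
    "inactive": "manual",
}


@dataclass(frozen=True)
class AlertThresholds:
    """Simple-alert bounds plus the complex/inactivity parameters.

    The printed clinical bounds are the diastolic >=105 mmHg and systolic
    >=170 mmHg simple alerts; the low-BP and heart-rate bounds are
    program-configurable safety nets.  ``complex_consecutive_k`` is the run
    length of consecutive off-target readings that fires a complex alert
    (default 4 = one full measurement day); ``inactivity_window_days`` is
    the inactivity window x.
    """

    simple_sbp_high: float = 170.0
    simple_dbp_high: float = 105.0
    simple_sbp_low: float = 90.0
    simple_dbp_low: float = 50.0
    simple_hr_high: float = 110.0
    simple_hr_low: float = 45.0
    complex_consecutive_k: int = 4
    #: when True a reading is complex-off-target only if SBP and DBP are
    #: both at/above target (combination-of-vitals rule); default is either
    complex_conjunctive: bool = False
    inactivity_window_days: int = 7

    def __post_init__(self) -> None:
        for vital in ("sbp", "dbp", "hr"):
            hi = getattr(self, f"simple_{vital}_high")
            lo = getattr(self, f"simple_{vital}_low")
            if hi <= lo:
                raise ConfigurationError(f"simple_{vital}_high", "high bound must exceed low bound")
        if self.complex_consecutive_k < 2:
            raise ConfigurationError("complex_consecutive_k", "must be >= 2")
        if self.inactivity_window_days < 1:
            raise ConfigurationError("inactivity_window_days", "must be >= 1")

    def bound(self, alert_type: str) -> float:
        return float(getattr(self, alert_type))


@dataclass(frozen=True)
class Alert:
    alert_id: str
    user_id: str
    trigger_date: date
    alert_type: str
    source_measurement_ids: tuple[str, ...] = ()
    routing: Optional[str] = None
    excess: Optional[float] = None


class RoutingPolicy(dict):
    """alert_type -> 'auto' | 'manual'; must be total over ALERT_TYPES."""

    def route(self, alert_type: str) -> str:
        try:
            return self[alert_type]
        except KeyError:
            raise ConfigurationError("routing", f"no routing for alert type {alert_type!r}")


def default_policy() -> RoutingPolicy:
    return RoutingPolicy(DEFAULT_ROUTING)


# ---------------------------------------------------------------------------
# scalar detectors (the per-event reference semantics)
# ---------------------------------------------------------------------------

def detect_simple(measurement: Measurement, thresholds: AlertThresholds) -> list[Alert]:
    """Simple alerts for one taken reading — one alert per violated bound."""
    if not measurement.taken:
        raise ContractViolation("detect_simple requires a taken measurement")
    alerts: list[Alert] = []
    for atype, (vital, direction, attr) in SIMPLE_RULES.items():
        value = getattr(measurement, vital)
        bound = thresholds.bound(attr)
        hit = value >= bound if direction == "high" else value <= bound
        if hit:
            excess = value - bound if direction == "high" else bound - value
            alerts.append(
                Alert(
                    alert_id=f"{measurement.user_id}:{measurement.date.isoformat()}:{atype}:0",
                    user_id=measurement.user_id,
                    trigger_date=measurement.date,
                    alert_type=atype,
                    source_measurement_ids=(measurement.measurement_id,),
                    excess=float(excess),
                )
            )
    return alerts


# ---------------------------------------------------------------------------
# vectorized detectors over the measurement log DataFrame
# ---------------------------------------------------------------------------

def _sorted_user_log(log: pd.DataFrame) -> pd.DataFrame:
    df = log.copy()
    df["date"] = pd.to_datetime(df["date"])
    if "measurement_id" not in df.columns:
        df["measurement_id"] = (
            df["user_id"] + ":" + df["date"].dt.strftime("%Y-%m-%d") + ":" + df["slot"]
        )
    df["_slot_order"] = df["slot"].map(SLOT_ORDER)
    return df.sort_values(["user_id", "date", "_slot_order"], kind="mergesort")


def _detect_simple_frame(taken: pd.DataFrame, thresholds: AlertThresholds) -> list[dict]:
    rows: list[dict] = []
    for atype, (vital, direction, attr) in SIMPLE_RULES.items():
        bound = thresholds.bound(attr)
        v = taken[vital].astype(float)
        mask = v >= bound if direction == "high" else v <= bound
        sub = taken.loc[mask]
        excess = (sub[vital].astype(float) - bound) if direction == "high" else (
            bound - sub[vital].astype(float)
        )
        rows.extend(
            {
                "user_id": uid,
                "trigger_date": d,
                "alert_type": atype,
                "source_measurement_ids": (mid,),
                "excess": float(ex),
            }
            for uid, d, mid, ex in zip(
                sub["user_id"], sub["date"], sub["measurement_id"], excess
            )
        )
    return rows


def _level_segments(user_log: pd.DataFrame):
    """Yield (level, frame) segments of contiguous protocol level."""
    levels = user_log["protocol_level"].to_numpy()
    change = np.flatnonzero(np.diff(levels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(levels)]))
    for s, e in zip(starts, ends):
        yield int(levels[s]), user_log.iloc[s:e]


def _detect_complex_frame(
    log_sorted: pd.DataFrame, ladder: ProtocolLadder, thresholds: AlertThresholds
) -> list[dict]:
    rows: list[dict] = []
    k = thresholds.complex_consecutive_k
    for uid, user_log in log_sorted.groupby("user_id", sort=True):
        for level, seg in _level_segments(user_log):
            proto = ladder.by_level(level)
            taken = seg[seg["taken"]]
            # off-target runs over consecutive taken readings
            sbp_off = (taken["sbp"].astype(float) >= proto.sbp_target).to_numpy()
            dbp_off = (taken["dbp"].astype(float) >= proto.dbp_target).to_numpy()
            off = (sbp_off & dbp_off) if thresholds.complex_conjunctive else (sbp_off | dbp_off)
            ids = taken["measurement_id"].to_numpy()
            dates = taken["date"].to_numpy()
            i = 0
            n = len(off)
            while i < n:
                if off[i]:
                    j = i
                    while j < n and off[j]:
                        j += 1
                    if j - i >= k:
                        rows.append(
                            {
                                "user_id": uid,
                                "trigger_date": pd.Timestamp(dates[i + k - 1]),
                                "alert_type": "complex_off_target",
                                "source_measurement_ids": tuple(ids[i:j]),
                                "excess": None,
                            }
                        )
                    i = j
                else:
                    i += 1
            # on-target measurement weeks -> switch/feedback alerts
            interval = proto.week_interval_days
            seg_start = seg["date"].iloc[0]
            week_id = ((seg["date"] - seg_start).dt.days // interval).to_numpy()
            for w in np.unique(week_id):
                wk = seg.iloc[np.flatnonzero(week_id == w)]
                wk_taken = wk[wk["taken"]]
                outcome = evaluate_week(
                    wk_taken["sbp"].astype(float).to_numpy(),
                    wk_taken["dbp"].astype(float).to_numpy(),
                    proto,
                    floor_level=min(ladder.levels),
                )
                if outcome.on_target:
                    rows.append(
                        {
                            "user_id": uid,
                            "trigger_date": wk["date"].iloc[-1],
                            "alert_type": "complex_on_target_switch",
                            "source_measurement_ids": tuple(wk_taken["measurement_id"]),
                            "excess": None,
                        }
                    )
    return rows


def _detect_missed_frame(log_sorted: pd.DataFrame, thresholds: AlertThresholds) -> list[dict]:
    rows: list[dict] = []
    x = thresholds.inactivity_window_days
    for uid, user_log in log_sorted.groupby("user_id", sort=True):
        missed = user_log[~user_log["taken"]]
        rows.extend(
            {
                "user_id": uid,
                "trigger_date": d,
                "alert_type": "overdue",
                "source_measurement_ids": (mid,),
                "excess": None,
            }
            for d, mid in zip(missed["date"], missed["measurement_id"])
        )
        # inactive: maximal runs of all-missed measurement-week days
        per_day = user_log.groupby("date", sort=True)["taken"].any()
        dead = (~per_day).to_numpy()
        days = per_day.index.to_numpy()
        i = 0
        n = len(dead)
        while i < n:
            if dead[i]:
                j = i
                while j < n and dead[j]:
                    j += 1
                if j - i >= x:
                    rows.append(
                        {
                            "user_id": uid,
                            "trigger_date": pd.Timestamp(days[i + x - 1]),
                            "alert_type": "inactive",
                            "source_measurement_ids": (),
                            "excess": None,
                        }
                    )
                i = j
            else:
                i += 1
    return rows


def _assemble(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return pd.DataFrame(columns=ALERT_COLUMNS)
    df = pd.DataFrame(rows)
    df["trigger_date"] = pd.to_datetime(df["trigger_date"])
    df = df.sort_values(["user_id", "trigger_date", "alert_type"], kind="mergesort")
    ordinal = df.groupby(["user_id", "trigger_date", "alert_type"]).cumcount()
    df["alert_id"] = (
        df["user_id"]
        + ":"
        + df["trigger_date"].dt.strftime("%Y-%m-%d")
        + ":"
        + df["alert_type"]
        + ":"
        + ordinal.astype(str)
    )
    df["routing"] = pd.NA
    df["source_measurement_ids"] = df["source_measurement_ids"].map(tuple)
    return df[ALERT_COLUMNS].reset_index(drop=True)


def detect_complex(
    log: pd.DataFrame,
    protocol_or_ladder,
    thresholds: AlertThresholds,
) -> pd.DataFrame:
    """Complex alerts for one user's time-ordered measurement log.

    Accepts a single :class:`MonitoringProtocol` (applied to all rows) or a
    :class:`ProtocolLadder` (rows carry their own ``protocol_level``).
    """
    if log["user_id"].nunique() > 1:
        raise ContractViolation("detect_complex expects a single user's log")
    df = log.copy()
    if isinstance(protocol_or_ladder, MonitoringProtocol):
        proto = protocol_or_ladder
        df["protocol_level"] = proto.level
        ladder = ProtocolLadder((proto,)) if proto.level == 0 else None
        if ladder is None:
            # wrap in a minimal valid ladder ending at level 0
            chronic = MonitoringProtocol(
                "chronic-floor", 0, proto.sbp_target - 1, proto.dbp_target - 1,
                proto.week_interval_days,
            )
            ladder = ProtocolLadder((proto, chronic))
    else:
        ladder = protocol_or_ladder
    if not pd.to_datetime(df["date"]).is_monotonic_increasing:
        raise ContractViolation("measurements must be sorted by time")
    return _assemble(_detect_complex_frame(_sorted_user_log(df), ladder, thresholds))


def detect_missed(log: pd.DataFrame, thresholds: AlertThresholds) -> pd.DataFrame:
    """Overdue and inactive alerts from the scheduled-slot log.

    The log has one row per scheduled slot (taken or not), so the schedule
    and the measurements cover the same range by construction.
    """
    return _assemble(_detect_missed_frame(_sorted_user_log(log), thresholds))


def route_alerts(alerts: pd.DataFrame, policy: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Assign auto/manual routing to every alert per the (total) policy."""
    policy = RoutingPolicy(policy or DEFAULT_ROUTING)
    out = alerts.copy()
    unmapped = set(out["alert_type"].unique()) - set(policy)
    if unmapped:
        raise ConfigurationError("routing", f"no routing for alert types {sorted(unmapped)}")
    out["routing"] = out["alert_type"].map(policy)
    return out


def run_engine(
    log: pd.DataFrame,
    users: Optional[pd.DataFrame] = None,
    ladder: Optional[ProtocolLadder] = None,
    thresholds: Optional[AlertThresholds] = None,
    policy: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Full detection pass: simple + complex + missed alerts, routed.

    Deterministic for fixed inputs; every alert lists its source
    measurement ids.  If the log lacks a ``protocol_level`` column, each
    user's ``start_protocol_level`` (from ``users``) is held fixed, or
    chronic level 0 when no users table is given.
    """
    ladder = ladder or build_default_ladder()
    thresholds = thresholds or AlertThresholds()
    log = log.copy()
    log["date"] = pd.to_datetime(log["date"])
    if "measurement_id" not in log.columns:
        log["measurement_id"] = (
            log["user_id"] + ":" + log["date"].dt.strftime("%Y-%m-%d") + ":" + log["slot"]
        )
    if "protocol_level" not in log.columns:
        if users is not None and "start_protocol_level" in users.columns:
            levels = users.set_index("user_id")["start_protocol_level"]
            log["protocol_level"] = log["user_id"].map(levels).fillna(0).astype(int)
        else:
            log["protocol_level"] = 0
    sorted_log = _sorted_user_log(log)
    taken = sorted_log[sorted_log["taken"]]
    rows = _detect_simple_frame(taken, thresholds)
    rows += _detect_complex_frame(sorted_log, ladder, thresholds)
    rows += _detect_missed_frame(sorted_log, thresholds)
    alerts = _assemble(rows)
    return route_alerts(alerts, policy)
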