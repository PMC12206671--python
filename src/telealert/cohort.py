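"""Seeded synthetic cohort generator for a home-BP telemonitoring program.

Emulates the statistical structure of a one-year hypertension
telemonitoring population: ~174 users active ~207 days on average, ~45%
enrolling directly into the chronic (monthly) algorithm, producing on the
order of 30,000 scheduled home BP/HR measurements, with a small elevated-BP
subgroup that concentrates most of the manually processed alert burden.

Per-user true means are drawn from a two-component mixture (background +
elevated subgroup); scheduled slots follow the user's current protocol with
automatic week-by-week switching; each slot is taken with a per-user
adherence probability; a fraction of users drop out mid-study, creating
inactivity cases.  All randomness flows through one seeded NumPy generator,
so identical configs and seeds give byte-identical logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from ._common import SLOT_LABELS, ConfigurationError
from .protocols import (
    MEASUREMENT_WEEK_DAYS,
    ProtocolLadder,
    WeekRule,
    build_default_ladder,
    evaluate_week,
)

MEASUREMENT_COLUMNS = [
    "measurement_id",
    "user_id",
    "date",
    "slot",
    "sbp",
    "dbp",
    "hr",
    "taken",
    "protocol_level",
]

USER_COLUMNS = [
    "user_id",
    "enrollment_date",
    "active_days",
    "start_protocol_level",
    "true_mean_sbp",
    "true_mean_dbp",
    "true_mean_hr",
    "adherence_p",
    "high_alert_member",
    "dropout_date",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Distributions of per-user true means are (location, spread) pairs of a
    normal; ``adherence_beta`` are the (a, b) parameters of a Beta
    distribution of the per-slot take probability.  ``high_alert_frac``
    users form an elevated-BP subgroup whose true means are shifted by
    ``high_alert_shift_*`` mmHg.
    """

    n_users: int = 174
    study_start: date = date(2022, 6, 1)
    study_end: date = date(2023, 5, 31)  # 365-day window
    frac_chronic_start: float = 0.45
    mean_active_days: int = 207
    user_mean_sbp_dist: tuple[float, float] = (142.0, 10.0)
    user_mean_dbp_dist: tuple[float, float] = (88.0, 7.0)
    user_mean_hr_dist: tuple[float, float] = (72.0, 8.0)
    within_user_sd_sbp: float = 10.0
    within_user_sd_dbp: float = 6.0
    within_user_sd_hr: float = 5.0
    adherence_beta: tuple[float, float] = (6.0, 4.0)
    adherence_fixed: Optional[float] = None  # degenerate adherence overriding the Beta
    high_alert_frac: float = 0.15
    high_alert_shift_sbp: float = 25.0
    high_alert_shift_dbp: float = 15.0
    dropout_frac: float = 0.08
    week_rule: WeekRule = "mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ConfigurationError("n_users", "must be >= 1")
        for name in ("frac_chronic_start", "high_alert_frac", "dropout_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(name, "must be a proportion in [0, 1]")
        for name in ("within_user_sd_sbp", "within_user_sd_dbp", "within_user_sd_hr"):
            if getattr(self, name) < 0:
                raise ConfigurationError(name, "spread must be >= 0")
        for name in ("user_mean_sbp_dist", "user_mean_dbp_dist", "user_mean_hr_dist"):
            if getattr(self, name)[1] < 0:
                raise ConfigurationError(name, "spread must be >= 0")
        if any(p <= 0 for p in self.adherence_beta):
            raise ConfigurationError("adherence_beta", "Beta parameters must be positive")
        if self.adherence_fixed is not None and not 0.0 <= self.adherence_fixed <= 1.0:
            raise ConfigurationError("adherence_fixed", "must be a probability in [0, 1]")
        if self.study_end <= self.study_start:
            raise ConfigurationError("study_end", "must be after study_start")
        if self.mean_active_days < 1 or self.mean_active_days > self.horizon_days:
            raise ConfigurationError("mean_active_days", "must fit inside the study window")

    @property
    def horizon_days(self) -> int:
        return (self.study_end - self.study_start).days + 1


@dataclass(frozen=True)
class User:
    user_id: str
    enrollment_date: date
    active_days: int
    start_protocol_level: int
    true_mean_sbp: float
    true_mean_dbp: float
    true_mean_hr: float
    adherence_p: float
    high_alert_member: bool
    dropout_date: Optional[date] = None


@dataclass(frozen=True)
class Measurement:
    """One scheduled slot: a taken reading or a missed slot (no vitals)."""

    user_id: str
    date: date
    slot: str
    sbp: Optional[float]
    dbp: Optional[float]
    hr: Optional[float]
    taken: bool
    protocol_level: int = 0

    def __post_init__(self) -> None:
        if self.taken:
            if self.sbp is None or self.dbp is None or self.hr is None:
                raise ValueError("taken measurement must carry vitals")
            if not (self.sbp > self.dbp > 0 and self.hr > 0):
                raise ValueError("vitals must be positive with sbp > dbp")
        elif any(v is not None for v in (self.sbp, self.dbp, self.hr)):
            raise ValueError("missed slot must not carry vitals")

    @property
    def measurement_id(self) -> str:
        return measurement_id(self.user_id, self.date, self.slot)


def measurement_id(user_id: str, d: date, slot: str) -> str:
    return f"{user_id}:{d.isoformat()}:{slot}"


def draw_users(config: CohortConfig, rng: np.random.Generator) -> list[User]:
    """Draw per-user latent parameters (no measurement simulation).

    Active-day spans are uniform on an interval symmetric around
    ``mean_active_days`` and capped at the window length; enrollment is
    uniform over the dates that let the span fit (staggered enrollment).
    """
    horizon = config.horizon_days
    lo = max(1, 2 * config.mean_active_days - horizon)
    hi = min(horizon, 2 * config.mean_active_days - lo)
    users: list[User] = []
    width = len(str(config.n_users))
    for i in range(config.n_users):
        uid = f"u{i + 1:0{width}d}"
        high = bool(rng.random() < config.high_alert_frac)
        msbp, ssbp = config.user_mean_sbp_dist
        mdbp, sdbp = config.user_mean_dbp_dist
        mhr, shr = config.user_mean_hr_dist
        mean_sbp = rng.normal(msbp, ssbp) + (config.high_alert_shift_sbp if high else 0.0)
        mean_dbp = rng.normal(mdbp, sdbp) + (config.high_alert_shift_dbp if high else 0.0)
        mean_hr = rng.normal(mhr, shr)
        adherence = (
            config.adherence_fixed
            if config.adherence_fixed is not None
            else float(rng.beta(*config.adherence_beta))
        )
        active = int(rng.integers(lo, hi + 1))
        latest_start = horizon - active
        start_offset = int(rng.integers(0, latest_start + 1))
        enrollment = config.study_start + timedelta(days=start_offset)
        level = 0 if rng.random() < config.frac_chronic_start else int(rng.integers(1, 5))
        dropout: Optional[date] = None
        if rng.random() < config.dropout_frac:
            frac = rng.uniform(0.3, 0.9)
            dropout = enrollment + timedelta(days=int(frac * active))
        users.append(
            User(
                user_id=uid,
                enrollment_date=enrollment,
                active_days=active,
                start_protocol_level=level,
                true_mean_sbp=float(mean_sbp),
                true_mean_dbp=float(mean_dbp),
                true_mean_hr=float(mean_hr),
                adherence_p=adherence,
                high_alert_member=high,
                dropout_date=dropout,
            )
        )
    return users


def _simulate_user_log(
    user: User, ladder: ProtocolLadder, config: CohortConfig, rng: np.random.Generator
) -> list[tuple]:
    """Simulate one user's scheduled slots with week-by-week switching."""
    rows: list[tuple] = []
    end = user.enrollment_date + timedelta(days=user.active_days)
    floor = min(ladder.levels)
    level = user.start_protocol_level
    block_start = user.enrollment_date
    while block_start < end:
        proto = ladder.by_level(level)
        labels = SLOT_LABELS[: proto.measurements_per_day]
        week_sbp: list[float] = []
        week_dbp: list[float] = []
        for d_off in range(MEASUREMENT_WEEK_DAYS):
            day = block_start + timedelta(days=d_off)
            if day >= end:
                break
            dropped = user.dropout_date is not None and day >= user.dropout_date
            for slot in labels:
                taken = (not dropped) and (rng.random() < user.adherence_p)
                if taken:
                    sbp = round(user.true_mean_sbp + rng.normal(0, config.within_user_sd_sbp))
                    dbp = round(user.true_mean_dbp + rng.normal(0, config.within_user_sd_dbp))
                    hr = round(user.true_mean_hr + rng.normal(0, config.within_user_sd_hr))
                    dbp = min(dbp, sbp - 10)  # enforce sbp > dbp with a pulse-pressure floor
                    dbp = max(dbp, 20)
                    sbp = max(sbp, dbp + 10)
                    hr = max(hr, 30)
                    week_sbp.append(sbp)
                    week_dbp.append(dbp)
                    rows.append(
                        (
                            measurement_id(user.user_id, day, slot),
                            user.user_id,
                            day,
                            slot,
                            int(sbp),
                            int(dbp),
                            int(hr),
                            True,
                            level,
                        )
                    )
                else:
                    rows.append(
                        (
                            measurement_id(user.user_id, day, slot),
                            user.user_id,
                            day,
                            slot,
                            None,
                            None,
                            None,
                            False,
                            level,
                        )
                    )
        outcome = evaluate_week(
            week_sbp, week_dbp, proto, floor_level=floor, rule=config.week_rule
        )
        level = outcome.new_level
        block_start += timedelta(days=proto.week_interval_days)
    return rows


def generate_cohort(
    config: CohortConfig, ladder: Optional[ProtocolLadder] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (users, measurement log) as DataFrames.

    The measurement log has one row per *scheduled* slot; missed slots carry
    ``taken=False`` and no vitals.  Fully reproducible for a fixed config
    (the seed lives in the config).
    """
    ladder = ladder or build_default_ladder()
    rng = np.random.default_rng(config.seed)
    users = draw_users(config, rng)
    rows: list[tuple] = []
    for user in users:
        rows.extend(_simulate_user_log(user, ladder, config, rng))
    log = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    log["date"] = pd.to_datetime(log["date"])
    for col in ("sbp", "dbp", "hr"):
        log[col] = log[col].astype("Float64")
    users_df = pd.DataFrame(
        [
            {
                "user_id": u.user_id,
                "enrollment_date": pd.Timestamp(u.enrollment_date),
                "active_days": u.active_days,
                "start_protocol_level": u.start_protocol_level,
                "true_mean_sbp": u.true_mean_sbp,
                "true_mean_dbp": u.true_mean_dbp,
                "true_mean_hr": u.true_mean_hr,
                "adherence_p": u.adherence_p,
                "high_alert_member": u.high_alert_member,
                "dropout_date": pd.Timestamp(u.dropout_date) if u.dropout_date else pd.NaT,
            }
            for u in users
        ],
        columns=USER_COLUMNS,
    )
    return users_df, log


def calibration_report(
    users: pd.DataFrame,
    log: pd.DataFrame,
    config: Optional[CohortConfig] = None,
    *,
    measurement_target: int = 30_184,
    tolerance: float = 0.2,
) -> dict:
    """Realized cohort statistics vs configured/targeted values.

    Reports user count, mean active days, taken-measurement total and
    chronic-start fraction, flagging deviations beyond ``tolerance``
    (relative) from the calibration target for measurement volume.
    """
    if len(users) == 0:
        raise ValueError("empty cohort")
    n_meas = int(log["taken"].sum())
    report = {
        "n_users": int(len(users)),
        "mean_active_days": float(users["active_days"].mean()),
        "n_measurements": n_meas,
        "n_scheduled_slots": int(len(log)),
        "chronic_start_fraction": float((users["start_protocol_level"] == 0).mean()),
        "measurement_target": measurement_target,
        "measurements_within_tolerance": bool(
            abs(n_meas - measurement_target) <= tolerance * measurement_target
        ),
    }
    if config is not None:
        report["config_n_users"] = config.n_users
        report["config_mean_active_days"] = config.mean_active_days
        report["config_frac_chronic_start"] = config.frac_chronic_start
    return report
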