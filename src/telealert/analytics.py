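"""Descriptive summaries of the alert and action logs, plus concentration.

Mirrors the standard reporting layout of a telemonitoring service
evaluation: an alert table (totals, auto/manual split, per-family
breakdown, manual alerts per user), an action table (administrative vs
clinical with clinical subtypes), and a top-user concentration analysis
quantifying how much of the burden a small fraction of users generates
(alert-fatigue focus).  All percentages are computed from unrounded ratios
and rounded half-up exactly once.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._common import pct, round_half_up
from .workflow import CLINICAL_SUBTYPES

MANUAL_FAMILIES = ("simple", "complex", "missed")


def _family(alert_type: str) -> str:
    if alert_type.startswith("simple"):
        return "simple"
    if alert_type.startswith("complex"):
        return "complex"
    return "missed"  # overdue / inactive


@dataclass(frozen=True)
class AlertSummary:
    """Alert-log totals with the fixed rounding convention.

    Percentage fields are None when their denominator is zero (undefined
    percentage, never a division failure).
    """

    n_users: int
    mean_active_days: Optional[float]
    n_measurements: int
    n_alerts: int
    pct_alerts_of_measurements: Optional[int]
    n_auto: int
    pct_auto_of_alerts: Optional[int]
    n_auto_complex: int
    pct_auto_complex: Optional[int]
    n_auto_missed: int
    pct_auto_missed: Optional[int]
    n_manual: int
    pct_manual_of_alerts: Optional[int]
    n_manual_simple: int
    pct_manual_simple: Optional[int]
    n_manual_complex: int
    pct_manual_complex: Optional[int]
    n_manual_missed: int
    pct_manual_missed: Optional[int]
    manual_alerts_per_user: Optional[int]

    def __post_init__(self) -> None:
        assert self.n_auto + self.n_manual == self.n_alerts
        assert self.n_auto_complex + self.n_auto_missed <= self.n_auto
        assert (
            self.n_manual_simple + self.n_manual_complex + self.n_manual_missed
            <= self.n_manual
        )

    @classmethod
    def from_counts(
        cls,
        *,
        n_users: int,
        n_measurements: int,
        n_auto_complex: int,
        n_auto_missed: int,
        n_manual_simple: int,
        n_manual_complex: int,
        n_manual_missed: int,
        n_auto_simple: int = 0,
        mean_active_days: Optional[float] = None,
    ) -> "AlertSummary":
        """Build a summary from raw counts (the printed-table arithmetic)."""
        n_auto = n_auto_simple + n_auto_complex + n_auto_missed
        n_manual = n_manual_simple + n_manual_complex + n_manual_missed
        n_alerts = n_auto + n_manual
        return cls(
            n_users=n_users,
            mean_active_days=mean_active_days,
            n_measurements=n_measurements,
            n_alerts=n_alerts,
            pct_alerts_of_measurements=pct(n_alerts, n_measurements),
            n_auto=n_auto,
            pct_auto_of_alerts=pct(n_auto, n_alerts),
            n_auto_complex=n_auto_complex,
            pct_auto_complex=pct(n_auto_complex, n_auto),
            n_auto_missed=n_auto_missed,
            pct_auto_missed=pct(n_auto_missed, n_auto),
            n_manual=n_manual,
            pct_manual_of_alerts=pct(n_manual, n_alerts),
            n_manual_simple=n_manual_simple,
            pct_manual_simple=pct(n_manual_simple, n_manual),
            n_manual_complex=n_manual_complex,
            pct_manual_complex=pct(n_manual_complex, n_manual),
            n_manual_missed=n_manual_missed,
            pct_manual_missed=pct(n_manual_missed, n_manual),
            manual_alerts_per_user=(
                round_half_up(n_manual / n_users) if n_users else None
            ),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AlertSummary":
        return cls(**d)


def summarize_alerts(
    log: pd.DataFrame,
    alerts: pd.DataFrame,
    *,
    n_users: Optional[int] = None,
    mean_active_days: Optional[float] = None,
) -> AlertSummary:
    """Summarize a measurement log + alert log pair."""
    if n_users is None:
        n_users = int(log["user_id"].nunique()) if len(log) else 0
    n_measurements = int(log["taken"].sum()) if len(log) else 0
    if len(alerts) == 0:
        return AlertSummary.from_counts(
            n_users=n_users,
            n_measurements=n_measurements,
            n_auto_complex=0,
            n_auto_missed=0,
            n_manual_simple=0,
            n_manual_complex=0,
            n_manual_missed=0,
            mean_active_days=mean_active_days,
        )
    fam = alerts["alert_type"].map(_family)
    routing = alerts["routing"]

    def count(route: str, family: str) -> int:
        return int(((routing == route) & (fam == family)).sum())

    return AlertSummary.from_counts(
        n_users=n_users,
        n_measurements=n_measurements,
        n_auto_simple=count("auto", "simple"),
        n_auto_complex=count("auto", "complex"),
        n_auto_missed=count("auto", "missed"),
        n_manual_simple=count("manual", "simple"),
        n_manual_complex=count("manual", "complex"),
        n_manual_missed=count("manual", "missed"),
        mean_active_days=mean_active_days,
    )


@dataclass(frozen=True)
class ActionSummary:
    n_actions: int
    n_administrative: int
    pct_administrative: Optional[int]
    n_clinical: int
    pct_clinical: Optional[int]
    subtype_counts: dict
    subtype_pcts: dict

    def __post_init__(self) -> None:
        assert self.n_administrative + self.n_clinical == self.n_actions
        assert sum(self.subtype_counts.values()) == self.n_clinical

    @classmethod
    def from_counts(
        cls, n_administrative: int, subtype_counts: dict
    ) -> "ActionSummary":
        subtype_counts = {s: int(subtype_counts.get(s, 0)) for s in CLINICAL_SUBTYPES}
        n_clinical = sum(subtype_counts.values())
        n_actions = n_administrative + n_clinical
        return cls(
            n_actions=n_actions,
            n_administrative=n_administrative,
            pct_administrative=pct(n_administrative, n_actions),
            n_clinical=n_clinical,
            pct_clinical=pct(n_clinical, n_actions),
            subtype_counts=subtype_counts,
            subtype_pcts={s: pct(c, n_clinical) for s, c in subtype_counts.items()},
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ActionSummary":
        return cls(**d)


def summarize_actions(actions: pd.DataFrame) -> ActionSummary:
    """Summarize classified telemonitoring actions."""
    if len(actions) == 0:
        return ActionSummary.from_counts(0, {})
    if actions["action_class"].isna().any():
        raise ValueError("actions must be classified before summarizing")
    n_admin = int((actions["action_class"] == "administrative").sum())
    clin = actions[actions["action_class"] == "clinical"]
    counts = clin["clinical_subtype"].value_counts().to_dict()
    return ActionSummary.from_counts(n_admin, counts)


@dataclass(frozen=True)
class ConcentrationReport:
    """Share of each burden metric held by the top fraction of users."""

    top_fraction: float
    n_users: int
    n_top: int
    rank_metric: str
    top_user_ids: tuple
    shares: dict  # metric -> share in [0, 1]


def _per_user_counts(alerts: pd.DataFrame, actions: Optional[pd.DataFrame]) -> pd.DataFrame:
    fam = alerts["alert_type"].map(_family) if len(alerts) else pd.Series(dtype=object)
    manual = alerts["routing"] == "manual" if len(alerts) else pd.Series(dtype=bool)
    frames = {
        "simple_alerts": alerts.loc[fam == "simple", "user_id"],
        "complex_alerts": alerts.loc[fam == "complex", "user_id"],
        "manual_alerts": alerts.loc[manual, "user_id"],
        "manual_simple_alerts": alerts.loc[manual & (fam == "simple"), "user_id"],
        "manual_complex_alerts": alerts.loc[manual & (fam == "complex"), "user_id"],
    }
    if actions is not None and len(actions):
        frames["actions"] = actions["user_id"]
    counts = pd.DataFrame(
        {name: s.value_counts() for name, s in frames.items()}
    ).fillna(0).astype(int)
    counts.index.name = "user_id"
    return counts


def concentration(
    alerts: pd.DataFrame,
    actions: Optional[pd.DataFrame] = None,
    *,
    top_fraction: float = 0.15,
    rank_metric: str = "manual_alerts",
    user_ids: Optional[Sequence[str]] = None,
) -> ConcentrationReport:
    """Burden share of the top ``top_fraction`` of users.

    Users are ranked descending by ``rank_metric`` (ties broken by user_id
    ascending); the top ``ceil(f * n_users)`` users' share of every burden
    metric is reported.  ``user_ids`` fixes the user universe (so users with
    zero alerts still count in the denominator of n); defaults to users seen
    in the logs.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    counts = _per_user_counts(alerts, actions)
    if user_ids is not None:
        counts = counts.reindex(sorted(set(user_ids)), fill_value=0)
    if len(counts) == 0:
        raise ValueError("empty input: no users to rank")
    if rank_metric not in counts.columns:
        raise ValueError(f"unknown rank metric {rank_metric!r}")
    n_users = len(counts)
    n_top = int(np.ceil(top_fraction * n_users))
    # stable sort after ascending index sort -> ties broken by user_id
    ranked = counts.sort_index().sort_values(rank_metric, ascending=False, kind="mergesort")
    top = ranked.iloc[:n_top]
    totals = counts.sum()
    shares = {
        m: (float(top[m].sum() / totals[m]) if totals[m] > 0 else float("nan"))
        for m in counts.columns
    }
    return ConcentrationReport(
        top_fraction=top_fraction,
        n_users=n_users,
        n_top=n_top,
        rank_metric=rank_metric,
        top_user_ids=tuple(top.index),
        shares=shares,
    )


def lorenz_curve(alerts: pd.DataFrame, metric: str = "manual_alerts") -> pd.DataFrame:
    """Cumulative user fraction vs cumulative burden fraction (descending).

    Users sorted by burden descending; row i gives the fraction of users
    and of total burden covered by the i heaviest users.
    """
    counts = _per_user_counts(alerts, None)
    if metric not in counts.columns:
        raise ValueError(f"unknown metric {metric!r}")
    c = counts[metric].sort_values(ascending=False)
    n = len(c)
    total = c.sum()
    return pd.DataFrame(
        {
            "user_fraction": np.arange(1, n + 1) / n,
            "burden_fraction": (c.cumsum() / total).to_numpy() if total else np.nan,
        }
    )


def summary_to_json(summary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)


def alert_summary_from_json(path) -> AlertSummary:
    with open(path) as fh:
        return AlertSummary.from_dict(json.load(fh))


def action_summary_from_json(path) -> ActionSummary:
    with open(path) as fh:
        return ActionSummary.from_dict(json.load(fh))
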