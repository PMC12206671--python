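"""Counterfactual threshold scenario analysis for simple alerts.

Given the year's alert log, each scenario asks: *if a simple-alert bound
had been higher, how many of the manually processed alerts would still have
fired, and how much e-nurse time would have been saved?*  Survival is
decided on the absolute values of the original measurements (no cohort
re-simulation): an alert survives iff its source reading still meets the
new bound.  The administrative/clinical split among survivors is recomputed
empirically from the survivors' action classes (they skew clinical, since
milder exceedances — mostly administrative — are the ones removed), and
workloads are costed in proportion mode with the administrative share
carried at two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from ._common import DataError, pct, round_half_up, round_half_up_2dp
from .alerts import SIMPLE_RULES
from .workflow import WorkloadModel, workload_from_proportions


@dataclass(frozen=True)
class ScenarioSpec:
    """One counterfactual threshold adjustment for a simple alert type."""

    alert_type: str
    current_threshold: float
    new_threshold: float

    def __post_init__(self) -> None:
        if self.alert_type not in SIMPLE_RULES:
            raise ValueError(f"not a simple alert type: {self.alert_type!r}")
        direction = SIMPLE_RULES[self.alert_type][1]
        if direction == "high" and self.new_threshold < self.current_threshold:
            raise ValueError("reduction scenario needs new_threshold >= current for high alerts")
        if direction == "low" and self.new_threshold > self.current_threshold:
            raise ValueError("reduction scenario needs new_threshold <= current for low alerts")

    @property
    def vital(self) -> str:
        return SIMPLE_RULES[self.alert_type][0]

    @property
    def direction(self) -> str:
        return SIMPLE_RULES[self.alert_type][1]


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    n_alerts_current: int
    n_alerts_surviving: int
    n_alerts_removed: int
    pct_reduction: Optional[int]
    p_administrative_current: Optional[float]
    p_clinical_current: Optional[float]
    p_administrative_new: Optional[float]
    p_clinical_new: Optional[float]
    n_projected_administrative: int
    n_projected_clinical: int
    baseline_minutes: int
    new_minutes: int
    minutes_saved: int
    extrapolation_mode: str  # "empirical" | "carried" | "empty"

    @property
    def empty(self) -> bool:
        return self.extrapolation_mode == "empty"


def _source_values(alerts: pd.DataFrame, log: pd.DataFrame, vital: str) -> pd.Series:
    """Source-measurement vital for each (simple) alert, indexed like alerts."""
    src = alerts["source_measurement_ids"].map(
        lambda ids: ids[0] if len(ids) else None
    )
    if src.isna().any():
        raise DataError("simple alert without a source measurement id")
    values = log.set_index("measurement_id")[vital]
    out = src.map(values)
    if out.isna().any():
        missing = src[out.isna()].iloc[0]
        raise DataError(f"broken linkage: source measurement {missing!r} not in log")
    return out.astype(float)


def rescore_alerts(
    alerts: pd.DataFrame, log: pd.DataFrame, spec: ScenarioSpec
) -> pd.DataFrame:
    """Alert log under the new threshold: alerts of ``spec.alert_type``
    survive iff their source reading meets the new bound; all other alerts
    pass through untouched."""
    affected = alerts["alert_type"] == spec.alert_type
    if not affected.any():
        return alerts.copy()
    sub = alerts[affected]
    values = _source_values(sub, log, spec.vital)
    if spec.direction == "high":
        keep = values >= spec.new_threshold
    else:
        keep = values <= spec.new_threshold
    return pd.concat([alerts[~affected], sub[keep]]).sort_index()


def alert_action_classes(alerts: pd.DataFrame, actions: pd.DataFrame) -> pd.Series:
    """Action class of each manual alert (via its containing action)."""
    mapping: dict[str, str] = {}
    for ids, cls in zip(actions["member_alert_ids"], actions["action_class"]):
        for aid in ids:
            mapping[aid] = cls
    return alerts["alert_id"].map(mapping)


def extrapolate_processing(
    surviving_classes: pd.Series,
    *,
    carried_p_administrative: Optional[float] = None,
) -> tuple[Optional[float], Optional[float], int, int, str]:
    """Administrative/clinical proportions among surviving alerts.

    Empirical mode recomputes proportions from the survivors' labels
    (two-decimal carry); when labels are absent the current proportions are
    carried unchanged.  Returns (p_admin, p_clinical, n_admin_projected,
    n_clinical_projected, mode).
    """
    n = len(surviving_classes)
    if n == 0:
        return None, None, 0, 0, "empty"
    if surviving_classes.notna().all():
        p_admin = round_half_up_2dp(
            float((surviving_classes == "administrative").mean())
        )
        mode = "empirical"
    elif carried_p_administrative is not None:
        p_admin = round_half_up_2dp(carried_p_administrative)
        mode = "carried"
    else:
        raise DataError("survivors lack action classes and no carried proportion given")
    p_clin = round(1.0 - p_admin, 10)
    n_admin = round_half_up(p_admin * n)
    n_clin = n - n_admin
    return p_admin, p_clin, n_admin, n_clin, mode


def run_scenario(
    alerts: pd.DataFrame,
    log: pd.DataFrame,
    spec: ScenarioSpec,
    *,
    actions: Optional[pd.DataFrame] = None,
    workload: Optional[WorkloadModel] = None,
) -> ScenarioResult:
    """Evaluate one threshold scenario on the manually processed alerts.

    Baseline and new workloads are proportion-mode costs over the current
    and surviving alert counts; the saving is their difference.
    """
    workload = workload or WorkloadModel()
    manual = alerts[(alerts["alert_type"] == spec.alert_type) & (alerts["routing"] == "manual")]
    n_current = len(manual)
    classes = None
    if actions is not None and len(actions):
        classes = alert_action_classes(manual, actions)
    if n_current == 0:
        return ScenarioResult(
            spec, 0, 0, 0, None, None, None, None, None, 0, 0, 0, 0, 0, "empty"
        )
    if classes is not None and classes.notna().all():
        p_admin_cur: Optional[float] = round_half_up_2dp(
            float((classes == "administrative").mean())
        )
    else:
        p_admin_cur = None
    survivors = rescore_alerts(manual, log, spec)
    n_surv = len(survivors)
    n_removed = n_current - n_surv
    surv_classes = (
        classes.loc[survivors.index] if classes is not None else pd.Series(index=survivors.index, dtype=object)
    )
    p_admin_new, p_clin_new, n_proj_admin, n_proj_clin, mode = extrapolate_processing(
        surv_classes, carried_p_administrative=p_admin_cur
    )
    baseline = (
        workload_from_proportions(n_current, p_admin_cur, workload)
        if p_admin_cur is not None
        else 0
    )
    new = (
        workload_from_proportions(n_surv, p_admin_new, workload)
        if p_admin_new is not None
        else 0
    )
    return ScenarioResult(
        spec=spec,
        n_alerts_current=n_current,
        n_alerts_surviving=n_surv,
        n_alerts_removed=n_removed,
        pct_reduction=pct(n_removed, n_current),
        p_administrative_current=p_admin_cur,
        p_clinical_current=(round(1 - p_admin_cur, 10) if p_admin_cur is not None else None),
        p_administrative_new=p_admin_new,
        p_clinical_new=p_clin_new,
        n_projected_administrative=n_proj_admin,
        n_projected_clinical=n_proj_clin,
        baseline_minutes=baseline,
        new_minutes=new,
        minutes_saved=baseline - new,
        extrapolation_mode=mode,
    )


def scenario_time_saving(
    n_current: int,
    p_administrative_current: float,
    n_surviving: int,
    p_administrative_new: float,
    workload: Optional[WorkloadModel] = None,
) -> int:
    """Minutes saved: baseline proportion-mode cost minus the new cost."""
    workload = workload or WorkloadModel()
    baseline = workload_from_proportions(n_current, p_administrative_current, workload)
    new = workload_from_proportions(n_surviving, p_administrative_new, workload)
    return baseline - new


def scenario_table(
    specs: Iterable[ScenarioSpec],
    alerts: pd.DataFrame,
    log: pd.DataFrame,
    *,
    actions: Optional[pd.DataFrame] = None,
    workload: Optional[WorkloadModel] = None,
) -> pd.DataFrame:
    """One row per scenario spec; rows are independent and deterministic.

    A failing row is reported with its error message instead of aborting
    the other rows.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("specs must be non-empty")
    rows = []
    for spec in specs:
        base = {
            "alert_type": spec.alert_type,
            "current_threshold": spec.current_threshold,
            "new_threshold": spec.new_threshold,
        }
        try:
            r = run_scenario(alerts, log, spec, actions=actions, workload=workload)
        except Exception as exc:  # row-level isolation
            rows.append({**base, "error": str(exc)})
            continue
        rows.append(
            {
                **base,
                "n_alerts_current": r.n_alerts_current,
                "n_alerts_surviving": r.n_alerts_surviving,
                "n_alerts_removed": r.n_alerts_removed,
                "pct_reduction": r.pct_reduction,
                "p_administrative_current": r.p_administrative_current,
                "p_administrative_new": r.p_administrative_new,
                "n_projected_administrative": r.n_projected_administrative,
                "n_projected_clinical": r.n_projected_clinical,
                "baseline_minutes": r.baseline_minutes,
                "new_minutes": r.new_minutes,
                "minutes_saved": r.minutes_saved,
                "extrapolation_mode": r.extrapolation_mode,
                "error": None,
            }
        )
    return pd.DataFrame(rows)
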