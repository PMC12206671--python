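"""E-nurse workflow model: cluster manual alerts into actions and cost them.

All manually routed alerts generated by one user on one day are handled
together as a single *telemonitoring action*.  E-nurses work office days
only, so weekend alerts are consolidated into the following Monday's
action.  Each action is either administrative (bookkeeping in the platform
and EHR, no clinical consequence) or clinical (a telephone consultation or
secure digital message, with or without a treatment adjustment).

The study's administrative/clinical labels were human decisions; here they
are modelled stochastically with the observed marginals (77% administrative;
clinical subtypes 40/28/28/4) plus an optional magnitude covariate: actions
whose member alerts exceed their simple-alert bound by more are more likely
to need a clinical response.  Workload is costed at 5 minutes per
administrative and 10 minutes per clinical action.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._common import ConfigurationError, ContractViolation, round_half_up

CLINICAL_SUBTYPES = (
    "phone_no_adjust",
    "phone_adjust",
    "message_no_adjust",
    "message_adjust",
)

ACTION_COLUMNS = [
    "action_id",
    "user_id",
    "processing_date",
    "member_alert_ids",
    "n_alerts",
    "max_excess",
    "action_class",
    "clinical_subtype",
]


@dataclass(frozen=True)
class ActionClassModel:
    """Stochastic stand-in for the e-nurse's administrative/clinical call.

    ``p_administrative`` is the marginal probability an action is purely
    administrative; ``clinical_subtype_probs`` split the clinical actions
    into (phone, phone+adjustment, message, message+adjustment).  With
    ``use_covariate`` on, the clinical log-odds of each action are shifted
    by ``covariate_slope`` per mmHg of the action's (mean-centred) maximum
    simple-alert excess, so bigger threshold exceedances skew clinical
    while the marginal stays at ``p_administrative``.
    """

    p_administrative: float = 0.77
    clinical_subtype_probs: tuple[float, float, float, float] = (0.40, 0.28, 0.28, 0.04)
    use_covariate: bool = True
    covariate_slope: float = 0.05  # clinical log-odds per mmHg of excess
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_administrative <= 1.0:
            raise ConfigurationError("p_administrative", "must be in [0, 1]")
        probs = self.clinical_subtype_probs
        if len(probs) != 4 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(
                "clinical_subtype_probs", "must be 4 non-negative probabilities summing to 1"
            )


@dataclass(frozen=True)
class WorkloadModel:
    """Minutes of e-nurse time per action class."""

    minutes_administrative: float = 5.0
    minutes_clinical: float = 10.0

    def __post_init__(self) -> None:
        if self.minutes_administrative <= 0 or self.minutes_clinical <= 0:
            raise ConfigurationError("minutes", "workload minutes must be positive")


def processing_date(trigger: pd.Timestamp) -> pd.Timestamp:
    """Office-day processing date: weekdays same day, weekends next Monday."""
    wd = trigger.weekday()  # Mon=0 .. Sun=6
    if wd == 5:
        return trigger + pd.Timedelta(days=2)
    if wd == 6:
        return trigger + pd.Timedelta(days=1)
    return trigger


def cluster_actions(manual_alerts: pd.DataFrame) -> pd.DataFrame:
    """Cluster manually routed alerts into per-user per-processing-day actions.

    Every input alert ends up in exactly one action; Saturday and Sunday
    alerts join the following Monday's action.  Returned actions are
    unclassified (``action_class`` empty).
    """
    if len(manual_alerts) and not (manual_alerts["routing"] == "manual").all():
        raise ContractViolation("cluster_actions accepts only manually routed alerts")
    if len(manual_alerts) == 0:
        return pd.DataFrame(columns=ACTION_COLUMNS)
    df = manual_alerts.copy()
    df["trigger_date"] = pd.to_datetime(df["trigger_date"])
    df["processing_date"] = df["trigger_date"].map(processing_date)
    if "excess" not in df.columns:
        df["excess"] = np.nan
    df = df.sort_values(["user_id", "processing_date", "alert_id"], kind="mergesort")
    grouped = df.groupby(["user_id", "processing_date"], sort=True)
    actions = grouped.agg(
        member_alert_ids=("alert_id", tuple),
        n_alerts=("alert_id", "size"),
        max_excess=("excess", "max"),
    ).reset_index()
    actions["max_excess"] = actions["max_excess"].astype(float).fillna(0.0)
    actions["action_id"] = (
        actions["user_id"] + ":" + actions["processing_date"].dt.strftime("%Y-%m-%d")
    )
    actions["action_class"] = pd.NA
    actions["clinical_subtype"] = pd.NA
    return actions[ACTION_COLUMNS]


def _marginal_preserving_intercept(offsets: np.ndarray, target_mean: float) -> float:
    """Intercept c with mean(sigmoid(c + offsets)) = target_mean (bisection).

    The mean of a sigmoid over the offsets is monotone in c, so plain
    bisection converges; 60 iterations give far better than float precision
    on the probability scale.
    """
    lo, hi = -30.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if (1.0 / (1.0 + np.exp(-(mid + offsets)))).mean() < target_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_actions(
    actions: pd.DataFrame,
    model: Optional[ActionClassModel] = None,
    *,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Assign administrative/clinical labels (and clinical subtypes).

    Seeded and reproducible; with the covariate on, the per-action clinical
    probability is ``sigmoid(logit(1 - p_administrative) + slope * (excess -
    mean excess))`` so the marginal administrative share stays close to the
    configured value while high-excess actions skew clinical.
    """
    model = model or ActionClassModel()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    out = actions.copy()
    if len(out) == 0:
        return out
    p_clin_base = 1.0 - model.p_administrative
    if model.use_covariate and p_clin_base not in (0.0, 1.0):
        x = out["max_excess"].astype(float).fillna(0.0).to_numpy()
        offsets = model.covariate_slope * (x - x.mean())
        # choose the intercept so the cohort-mean clinical probability equals
        # the configured marginal (centring alone leaves a Jensen bias)
        intercept = _marginal_preserving_intercept(offsets, p_clin_base)
        p_clin = 1.0 / (1.0 + np.exp(-(intercept + offsets)))
    else:
        p_clin = np.full(len(out), p_clin_base)
    clinical = rng.random(len(out)) < p_clin
    out["action_class"] = np.where(clinical, "clinical", "administrative")
    subtype_idx = rng.choice(4, size=len(out), p=model.clinical_subtype_probs)
    out["clinical_subtype"] = np.where(
        clinical, np.asarray(CLINICAL_SUBTYPES, dtype=object)[subtype_idx], "none"
    )
    return out


@dataclass(frozen=True)
class WorkloadBreakdown:
    n_administrative: int
    n_clinical: int
    minutes_administrative: float
    minutes_clinical: float

    @property
    def total_minutes(self) -> float:
        return self.minutes_administrative + self.minutes_clinical


def compute_workload(
    actions: pd.DataFrame, model: Optional[WorkloadModel] = None
) -> WorkloadBreakdown:
    """Total e-nurse minutes for classified actions, by class."""
    model = model or WorkloadModel()
    if len(actions) == 0:
        return WorkloadBreakdown(0, 0, 0.0, 0.0)
    if actions["action_class"].isna().any():
        raise ContractViolation("compute_workload requires classified actions")
    n_admin = int((actions["action_class"] == "administrative").sum())
    n_clin = int((actions["action_class"] == "clinical").sum())
    return WorkloadBreakdown(
        n_administrative=n_admin,
        n_clinical=n_clin,
        minutes_administrative=n_admin * model.minutes_administrative,
        minutes_clinical=n_clin * model.minutes_clinical,
    )


def workload_from_proportions(
    n_alerts: int, p_administrative: float, model: Optional[WorkloadModel] = None
) -> int:
    """Minutes of e-nurse work for ``n_alerts`` at a given administrative share.

    Proportion-mode costing: ``round_half_up(n*p*m_admin + n*(1-p)*m_clin)``
    — the arithmetic used for scenario workload projections, where the
    administrative share is carried as a proportion rather than a count.
    """
    if not 0.0 <= p_administrative <= 1.0:
        raise ValueError("p_administrative must be in [0, 1]")
    model = model or WorkloadModel()
    return round_half_up(
        n_alerts * p_administrative * model.minutes_administrative
        + n_alerts * (1.0 - p_administrative) * model.minutes_clinical
    )
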