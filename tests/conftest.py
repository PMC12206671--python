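"""Shared fixtures: small synthetic cohorts and hand-built logs."""

from datetime import date

import pandas as pd
import pytest

from telealert import (
    AlertThresholds,
    CohortConfig,
    build_default_ladder,
    generate_cohort,
    run_engine,
)


@pytest.fixture(scope="session")
def ladder():
    return build_default_ladder()


@pytest.fixture(scope="session")
def small_config():
    # 15 users over half a year: big enough for every alert family to fire,
    # small enough for brute-force oracles
    return CohortConfig(
        n_users=15,
        study_start=date(2022, 6, 1),
        study_end=date(2022, 11, 30),
        mean_active_days=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config, ladder):
    return generate_cohort(small_config, ladder)


@pytest.fixture(scope="session")
def small_alerts(small_cohort, ladder):
    users, log = small_cohort
    return run_engine(log, users, ladder, AlertThresholds())


def make_log(rows):
    """Build a measurement log from (user, iso_date, slot, sbp, dbp, hr, taken)."""
    df = pd.DataFrame(
        rows, columns=["user_id", "date", "slot", "sbp", "dbp", "hr", "taken"]
    )
    df["date"] = pd.to_datetime(df["date"])
    df["measurement_id"] = (
        df["user_id"] + ":" + df["date"].dt.strftime("%Y-%m-%d") + ":" + df["slot"]
    )
    df["protocol_level"] = 0
    for col in ("sbp", "dbp", "hr"):
        df[col] = df[col].astype("Float64")
    return df


def make_alerts(rows):
    """Build an alert log from (user, iso_date, alert_type, routing[, excess])."""
    recs = []
    for i, row in enumerate(rows):
        user, d, atype, routing = row[:4]
        excess = row[4] if len(row) > 4 else None
        recs.append(
            {
                "alert_id": f"{user}:{d}:{atype}:{i}",
                "user_id": user,
                "trigger_date": pd.Timestamp(d),
                "alert_type": atype,
                "routing": routing,
                "source_measurement_ids": (),
                "excess": excess,
            }
        )
    cols = [
        "alert_id", "user_id", "trigger_date", "alert_type",
        "routing", "source_measurement_ids", "excess",
    ]
    return pd.DataFrame(recs, columns=cols)
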