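"""Alert engine: simple/complex/missed detection, routing, oracles."""

from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telealert import (
    AlertThresholds,
    ConfigurationError,
    ContractViolation,
    Measurement,
    default_policy,
    detect_complex,
    detect_missed,
    detect_simple,
    route_alerts,
    run_engine,
)
from telealert.cohort import measurement_id

from conftest import make_log


def brute_force_simple(log: pd.DataFrame, th: AlertThresholds) -> set:
    """Independent per-measurement scan: (measurement_id, alert_type) pairs."""
    hits = set()
    for r in log.itertuples():
        if not r.taken:
            continue
        if r.sbp >= th.simple_sbp_high:
            hits.add((r.measurement_id, "simple_sbp_high"))
        if r.sbp <= th.simple_sbp_low:
            hits.add((r.measurement_id, "simple_sbp_low"))
        if r.dbp >= th.simple_dbp_high:
            hits.add((r.measurement_id, "simple_dbp_high"))
        if r.dbp <= th.simple_dbp_low:
            hits.add((r.measurement_id, "simple_dbp_low"))
        if r.hr >= th.simple_hr_high:
            hits.add((r.measurement_id, "simple_hr_high"))
        if r.hr <= th.simple_hr_low:
            hits.add((r.measurement_id, "simple_hr_low"))
    return hits


def meas(sbp, dbp, hr=70, user="u1", d=date(2022, 6, 1), slot="morning-1"):
    return Measurement(user, d, slot, sbp, dbp, hr, True)


class TestDetectSimple:
    def test_dbp_106_crosses_inclusive_105_bound(self):
        alerts = detect_simple(meas(140, 106), AlertThresholds())
        assert [a.alert_type for a in alerts] == ["simple_dbp_high"]
        assert alerts[0].excess == 1.0

    def test_sbp_169_is_below_inclusive_170_bound(self):
        assert detect_simple(meas(169, 80), AlertThresholds()) == []

    def test_sbp_exactly_at_bound_fires(self):
        alerts = detect_simple(meas(170, 80), AlertThresholds())
        assert [a.alert_type for a in alerts] == ["simple_sbp_high"]

    def test_hypertensive_crisis_yields_two_alerts(self):
        alerts = detect_simple(meas(240, 130), AlertThresholds())
        assert {a.alert_type for a in alerts} == {"simple_sbp_high", "simple_dbp_high"}

    def test_low_bounds_inclusive(self):
        alerts = detect_simple(meas(90, 50, hr=45), AlertThresholds())
        assert {a.alert_type for a in alerts} == {
            "simple_sbp_low",
            "simple_dbp_low",
            "simple_hr_low",
        }

    def test_missed_measurement_is_contract_violation(self):
        missed = Measurement("u1", date(2022, 6, 1), "morning-1", None, None, None, False)
        with pytest.raises(ContractViolation):
            detect_simple(missed, AlertThresholds())


def chronic_week_log(values, user="u1", start=date(2022, 6, 6)):
    """A 7-day chronic measurement week; values = list of (sbp, dbp) or None."""
    slots = ["morning-1", "morning-2", "evening-1", "evening-2"]
    rows = []
    for i, v in enumerate(values):
        d = (pd.Timestamp(start) + pd.Timedelta(days=i // 4)).strftime("%Y-%m-%d")
        slot = slots[i % 4]
        if v is None:
            rows.append((user, d, slot, None, None, None, False))
        else:
            rows.append((user, d, slot, v[0], v[1], 70, True))
    return make_log(rows)


class TestDetectComplex:
    def test_four_consecutive_off_target_fire_once(self, ladder):
        log = chronic_week_log([(150, 96)] * 4 + [(120, 70)] * 24)
        alerts = detect_complex(log, ladder.chronic, AlertThresholds())
        off = alerts[alerts["alert_type"] == "complex_off_target"]
        assert len(off) == 1
        assert len(off.iloc[0]["source_measurement_ids"]) == 4

    def test_run_shorter_than_k_does_not_fire(self, ladder):
        log = chronic_week_log([(150, 96)] * 3 + [(120, 70)] * 25)
        alerts = detect_complex(log, ladder.chronic, AlertThresholds())
        assert (alerts["alert_type"] != "complex_off_target").all()

    def test_long_run_yields_single_alert(self, ladder):
        log = chronic_week_log([(150, 96)] * 12 + [(120, 70)] * 16)
        alerts = detect_complex(log, ladder.chronic, AlertThresholds())
        off = alerts[alerts["alert_type"] == "complex_off_target"]
        assert len(off) == 1
        assert len(off.iloc[0]["source_measurement_ids"]) == 12

    def test_missed_slots_do_not_break_a_run(self, ladder):
        log = chronic_week_log(
            [(150, 96), (150, 96), None, (150, 96), (150, 96)] + [(120, 70)] * 23
        )
        alerts = detect_complex(log, ladder.chronic, AlertThresholds())
        assert (alerts["alert_type"] == "complex_off_target").sum() == 1

    def test_conjunctive_rule_requires_both_vitals_off_target(self, ladder):
        # SBP high but DBP controlled: disjunctive fires, conjunctive does not
        log = chronic_week_log([(150, 80)] * 4 + [(120, 70)] * 24)
        either = detect_complex(log, ladder.chronic, AlertThresholds())
        both = detect_complex(
            log, ladder.chronic, AlertThresholds(complex_conjunctive=True)
        )
        assert (either["alert_type"] == "complex_off_target").sum() == 1
        assert (both["alert_type"] == "complex_off_target").sum() == 0

    def test_fully_on_target_week_emits_switch_alert(self, ladder):
        log = chronic_week_log([(120, 70)] * 28)
        alerts = detect_complex(log, ladder.chronic, AlertThresholds())
        assert (alerts["alert_type"] == "complex_on_target_switch").sum() == 1

    def test_multi_user_log_rejected(self, ladder):
        log = pd.concat(
            [chronic_week_log([(120, 70)] * 4), chronic_week_log([(120, 70)] * 4, user="u2")]
        )
        with pytest.raises(ContractViolation):
            detect_complex(log, ladder.chronic, AlertThresholds())


class TestDetectMissed:
    def test_one_missed_slot_one_overdue_no_inactive(self):
        log = chronic_week_log([None] + [(120, 70)] * 27)
        alerts = detect_missed(log, AlertThresholds())
        assert (alerts["alert_type"] == "overdue").sum() == 1
        assert (alerts["alert_type"] == "inactive").sum() == 0

    def test_whole_week_missed_28_overdue_one_inactive(self):
        log = chronic_week_log([None] * 28)
        alerts = detect_missed(log, AlertThresholds(inactivity_window_days=7))
        assert (alerts["alert_type"] == "overdue").sum() == 28
        assert (alerts["alert_type"] == "inactive").sum() == 1

    def test_six_dead_days_below_window_no_inactive(self):
        log = chronic_week_log([None] * 24 + [(120, 70)] * 4)
        alerts = detect_missed(log, AlertThresholds(inactivity_window_days=7))
        assert (alerts["alert_type"] == "inactive").sum() == 0

    def test_full_adherence_no_missed_alerts(self):
        log = chronic_week_log([(120, 70)] * 28)
        assert len(detect_missed(log, AlertThresholds())) == 0

    def test_every_overdue_references_one_missed_slot(self, small_cohort, small_alerts):
        _, log = small_cohort
        overdue = small_alerts[small_alerts["alert_type"] == "overdue"]
        missed_ids = set(log.loc[~log["taken"], "measurement_id"])
        assert len(overdue) <= len(log)
        for ids in overdue["source_measurement_ids"]:
            assert len(ids) == 1 and ids[0] in missed_ids
        # one overdue per missed slot, no duplicates
        assert overdue["source_measurement_ids"].map(lambda t: t[0]).is_unique
        assert len(overdue) == len(missed_ids)


class TestRouting:
    def test_default_policy_assignments(self):
        alerts = run_engine(chronic_week_log([(150, 106)] * 4 + [None] * 24))
        by_type = alerts.groupby("alert_type")["routing"].unique()
        assert list(by_type["overdue"]) == ["auto"]
        assert list(by_type["simple_dbp_high"]) == ["manual"]
        assert list(by_type["complex_off_target"]) == ["manual"]

    def test_unmapped_alert_type_is_config_error(self, small_alerts):
        policy = {k: "auto" for k in ["overdue"]}
        with pytest.raises(ConfigurationError):
            route_alerts(small_alerts, policy)

    def test_empty_alert_list_conserved(self):
        empty = pd.DataFrame(columns=["alert_type"])
        routed = route_alerts(empty, default_policy())
        assert len(routed) == 0

    def test_auto_plus_manual_equals_total_for_any_policy(self, small_alerts):
        rng = np.random.default_rng(0)
        for _ in range(5):
            policy = {t: rng.choice(["auto", "manual"]) for t in default_policy()}
            routed = route_alerts(small_alerts, policy)
            n_auto = (routed["routing"] == "auto").sum()
            n_manual = (routed["routing"] == "manual").sum()
            assert n_auto + n_manual == len(routed)


class TestEngineOracle:
    def test_simple_alerts_match_brute_force_scan(self, small_cohort, small_alerts):
        """Vectorized engine vs independent per-measurement scan (<=20 users)."""
        _, log = small_cohort
        th = AlertThresholds()
        expected = brute_force_simple(log, th)
        got = {
            (a.source_measurement_ids[0], a.alert_type)
            for a in small_alerts.itertuples()
            if a.alert_type.startswith("simple")
        }
        assert got == expected

    def test_engine_deterministic(self, small_cohort, ladder):
        users, log = small_cohort
        a1 = run_engine(log, users, ladder)
        a2 = run_engine(log, users, ladder)
        pd.testing.assert_frame_equal(a1, a2)

    def test_every_alert_traceable(self, small_cohort, small_alerts):
        _, log = small_cohort
        all_ids = set(log["measurement_id"])
        for a in small_alerts.itertuples():
            if a.alert_type == "inactive":
                assert a.source_measurement_ids == ()
            else:
                assert set(a.source_measurement_ids) <= all_ids

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        bump=st.integers(min_value=0, max_value=40),
        seed=st.integers(min_value=0, max_value=50),
    )
    def test_raising_high_threshold_never_increases_count(self, bump, seed):
        rng = np.random.default_rng(seed)
        n = 60
        rows = []
        for i in range(n):
            sbp = int(rng.normal(160, 25))
            dbp = int(rng.normal(95, 15))
            sbp = max(sbp, dbp + 10)
            rows.append(
                ("u1", "2022-06-06", ["morning-1", "morning-2", "evening-1", "evening-2"][i % 4],
                 sbp, max(dbp, 30), 70, True)
            )
        # distinct dates to keep slots unique
        rows = [
            (u, (pd.Timestamp(d) + pd.Timedelta(days=i // 4)).strftime("%Y-%m-%d"), s, a, b, h, t)
            for i, (u, d, s, a, b, h, t) in enumerate(rows)
        ]
        log = make_log(rows)
        base = AlertThresholds()
        raised = replace(base, simple_sbp_high=base.simple_sbp_high + bump)
        n_base = len(brute_force_simple(log, base) & {(m, "simple_sbp_high") for m in log["measurement_id"]})
        count = lambda th: (run_engine(log, thresholds=th)["alert_type"] == "simple_sbp_high").sum()
        assert count(raised) <= count(base)
        assert count(base) == n_base
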