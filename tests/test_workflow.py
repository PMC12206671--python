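"""Action clustering, stochastic classification and workload arithmetic."""

import numpy as np
import pandas as pd
import pytest

from telealert import (
    ActionClassModel,
    ContractViolation,
    WorkloadModel,
    classify_actions,
    cluster_actions,
    compute_workload,
    workload_from_proportions,
)
from telealert.workflow import processing_date

from conftest import make_alerts

# 2022-06-04 was a Saturday, 2022-06-05 a Sunday, 2022-06-06 a Monday
SAT, SUN, MON, TUE = "2022-06-04", "2022-06-05", "2022-06-06", "2022-06-07"


class TestClustering:
    def test_weekend_alerts_fold_into_monday_action(self):
        alerts = make_alerts(
            [("a", SAT, "simple_sbp_high", "manual"), ("a", SUN, "simple_dbp_high", "manual")]
        )
        actions = cluster_actions(alerts)
        assert len(actions) == 1
        act = actions.iloc[0]
        assert act["processing_date"] == pd.Timestamp(MON)
        assert act["n_alerts"] == 2

    def test_same_day_alerts_cluster_into_one_action(self):
        alerts = make_alerts([("a", TUE, f"t{i}", "manual") for i in range(3)])
        actions = cluster_actions(alerts)
        assert len(actions) == 1 and actions.iloc[0]["n_alerts"] == 3

    def test_clustering_is_per_user(self):
        alerts = make_alerts(
            [("a", TUE, "simple_sbp_high", "manual"), ("b", TUE, "simple_sbp_high", "manual")]
        )
        assert len(cluster_actions(alerts)) == 2

    def test_weekday_alerts_processed_same_day(self):
        alerts = make_alerts([("a", TUE, "simple_sbp_high", "manual")])
        assert cluster_actions(alerts).iloc[0]["processing_date"] == pd.Timestamp(TUE)

    def test_auto_alert_in_input_is_contract_violation(self):
        alerts = make_alerts([("a", TUE, "overdue", "auto")])
        with pytest.raises(ContractViolation):
            cluster_actions(alerts)

    def test_monday_and_prior_weekend_merge(self):
        alerts = make_alerts(
            [("a", SAT, "x", "manual"), ("a", MON, "y", "manual")]
        )
        actions = cluster_actions(alerts)
        assert len(actions) == 1 and actions.iloc[0]["n_alerts"] == 2

    def test_partition_of_manual_alerts(self, small_alerts):
        manual = small_alerts[small_alerts["routing"] == "manual"]
        actions = cluster_actions(manual)
        member_ids = [aid for ids in actions["member_alert_ids"] for aid in ids]
        assert len(member_ids) == len(manual)  # every alert in exactly one action
        assert len(set(member_ids)) == len(member_ids)
        assert set(member_ids) == set(manual["alert_id"])

    def test_no_weekend_processing_dates(self, small_alerts):
        manual = small_alerts[small_alerts["routing"] == "manual"]
        actions = cluster_actions(manual)
        assert (actions["processing_date"].dt.weekday < 5).all()

    @pytest.mark.parametrize(
        "day,expected",
        [(SAT, MON), (SUN, MON), (MON, MON), ("2022-06-10", "2022-06-10")],
    )
    def test_processing_date_calendar(self, day, expected):
        assert processing_date(pd.Timestamp(day)) == pd.Timestamp(expected)


class TestClassification:
    def _actions(self, n, excess=None):
        alerts = make_alerts(
            [
                ("u%05d" % i, TUE, "simple_sbp_high", "manual",
                 None if excess is None else excess[i])
                for i in range(n)
            ]
        )
        return cluster_actions(alerts)

    def test_degenerate_all_administrative(self):
        acts = classify_actions(self._actions(50), ActionClassModel(p_administrative=1.0))
        assert (acts["action_class"] == "administrative").all()
        assert (acts["clinical_subtype"] == "none").all()

    def test_degenerate_all_clinical(self):
        acts = classify_actions(self._actions(50), ActionClassModel(p_administrative=0.0))
        assert (acts["action_class"] == "clinical").all()
        assert set(acts["clinical_subtype"]) <= {
            "phone_no_adjust", "phone_adjust", "message_no_adjust", "message_adjust",
        }

    def test_marginal_administrative_share_calibrated(self):
        # 10,000 actions at defaults: within 3 sigma of 0.77
        rng = np.random.default_rng(3)
        acts = classify_actions(
            self._actions(10_000, excess=rng.exponential(10, 10_000)),
            ActionClassModel(seed=9),
        )
        share = (acts["action_class"] == "administrative").mean()
        sigma = np.sqrt(0.77 * 0.23 / 10_000)
        assert abs(share - 0.77) < 3 * sigma

    def test_higher_excess_raises_clinical_probability(self):
        rng = np.random.default_rng(4)
        excess = np.concatenate([np.zeros(4000), np.full(4000, 30.0)])
        acts = classify_actions(self._actions(8000, excess=excess), ActionClassModel(seed=5))
        merged = acts.assign(x=acts["max_excess"])
        low = merged[merged["x"] == 0]["action_class"].eq("clinical").mean()
        high = merged[merged["x"] == 30]["action_class"].eq("clinical").mean()
        assert high > low

    def test_same_seed_identical_labels(self):
        acts = self._actions(200)
        a = classify_actions(acts, ActionClassModel(seed=1))
        b = classify_actions(acts, ActionClassModel(seed=1))
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_probabilities_rejected(self):
        from telealert import ConfigurationError

        with pytest.raises(ConfigurationError):
            ActionClassModel(p_administrative=1.5)
        with pytest.raises(ConfigurationError):
            ActionClassModel(clinical_subtype_probs=(0.5, 0.5, 0.5, 0.5))


class TestWorkload:
    def test_study_scale_counts(self):
        # 1626 administrative + 475 clinical at 5/10 minutes
        acts = pd.DataFrame(
            {"action_class": ["administrative"] * 1626 + ["clinical"] * 475}
        )
        wl = compute_workload(acts)
        assert wl.total_minutes == 12_880
        assert wl.minutes_administrative == 8130 and wl.minutes_clinical == 4750

    def test_empty_actions_zero_minutes(self):
        assert compute_workload(pd.DataFrame(columns=["action_class"])).total_minutes == 0

    def test_one_of_each_is_15_minutes(self):
        acts = pd.DataFrame({"action_class": ["administrative", "clinical"]})
        assert compute_workload(acts).total_minutes == 15

    def test_unclassified_actions_rejected(self):
        acts = pd.DataFrame({"action_class": ["administrative", pd.NA]})
        with pytest.raises(ContractViolation):
            compute_workload(acts)

    def test_linearity_over_disjoint_sets(self, small_alerts):
        manual = small_alerts[small_alerts["routing"] == "manual"]
        acts = classify_actions(cluster_actions(manual), ActionClassModel(seed=2))
        half = len(acts) // 2
        a, b = acts.iloc[:half], acts.iloc[half:]
        assert (
            compute_workload(a).total_minutes + compute_workload(b).total_minutes
            == compute_workload(acts).total_minutes
        )


class TestProportionModeWorkload:
    def test_diastolic_baseline_6598_minutes(self):
        assert workload_from_proportions(1023, 0.71) == 6598

    def test_systolic_baseline_5631_minutes(self):
        assert workload_from_proportions(873, 0.71) == 5631

    @pytest.mark.parametrize("p", [0.0, 0.3, 0.71, 1.0])
    def test_zero_alerts_zero_minutes(self, p):
        assert workload_from_proportions(0, p) == 0

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            workload_from_proportions(10, 1.2)

    @pytest.mark.parametrize("n,n_admin", [(100, 77), (1023, 726), (873, 620), (7, 3)])
    def test_proportion_and_count_mode_agree_within_rounding(self, n, n_admin):
        # proportion-mode vs exact-count workload differ by < minutes_clinical
        model = WorkloadModel()
        exact = n_admin * 5 + (n - n_admin) * 10
        approx = workload_from_proportions(n, n_admin / n, model)
        assert abs(approx - exact) < model.minutes_clinical
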