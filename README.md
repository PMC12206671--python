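# telealert

Alert-burden simulation, e-nurse workload modelling and threshold scenario
analysis for home blood-pressure telemonitoring programs.

## The problem

Care-path-embedded telemonitoring programs for hypertension let patients
measure blood pressure at home on a scheduled cadence. Each measurement can
trigger alerts; some are handled automatically by the platform, the rest
are reviewed by specialized monitoring nurses (e-nurses). Programs of even
modest size generate tens of thousands of alerts a year, a classic
alert-fatigue setting: a small set of users typically generates most of the
manually processed alerts, and modest threshold changes can remove a large
share of the burden with limited clinical impact. Quantifying that
trade-off — *how many alerts would a +5 mmHg bound remove, and how many
e-nurse minutes would it save?* — is the job of this package.

`telealert` is for telemonitoring teams, health-services researchers and
methodologists who want a tested, reproducible pipeline for this analysis:
it simulates a realistic cohort (no patient data required), runs a
rule-based alert engine, models the nursing workflow, and evaluates
counterfactual threshold scenarios.

## The model

* **Protocol ladder.** Users sit on one of five measurement algorithms:
  four acute (targets 180/110 → 150/95 mmHg, weekly or biweekly
  measurement weeks) and one chronic (140/90 mmHg, one week per month).
  During a measurement week users measure 2× morning + 2× evening. A week
  whose mean SBP and DBP are both below target steps the user down one
  rung automatically.
* **Alerts.** *Simple*: one reading crosses a one-off bound (defaults
  SBP ≥170, DBP ≥105 mmHg; inclusive bounds). *Complex*: ≥ k = 4
  consecutive off-target readings (one alert per episode), or an on-target
  week (the auto-processed protocol-switch event). *Overdue/inactive*: a
  missed scheduled slot / ≥7 consecutive fully-missed measurement days.
  A routing policy maps each type to automatic or manual processing.
* **Workflow.** All manual alerts for one user on one day form a
  *telemonitoring action* (weekend alerts fold into Monday), classified
  administrative (p = 0.77) or clinical, costed at 5 and 10 minutes.
  Minutes in proportion mode are `round_half_up(n·p·5 + n·(1−p)·10)`.
* **Scenarios.** Raising a simple-alert bound keeps exactly the alerts
  whose original readings meet the new bound; the administrative share is
  re-estimated among survivors and the saving is the difference of
  proportion-mode workloads.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from telealert import (
    ActionClassModel, CohortConfig, ScenarioSpec, classify_actions,
    cluster_actions, compute_workload, concentration, generate_cohort,
    run_engine, run_scenario, summarize_actions, summarize_alerts,
)

users, log = generate_cohort(CohortConfig(seed=1))      # 174 users, 1 year
alerts = run_engine(log, users)                          # detect + route
manual = alerts[alerts.routing == "manual"]
actions = classify_actions(cluster_actions(manual), ActionClassModel(seed=2))

s = summarize_alerts(log, alerts, n_users=len(users))
print(s.n_measurements, s.n_alerts, s.pct_manual_of_alerts)  # 30164 32216 33

a = summarize_actions(actions)
print(a.n_actions, a.pct_administrative)                 # 4178 77
print(compute_workload(actions).total_minutes)           # 25760.0

c = concentration(alerts, actions, user_ids=list(users.user_id))
print(round(c.shares["manual_alerts"], 2))               # 0.77

r = run_scenario(alerts, log, ScenarioSpec("simple_dbp_high", 105, 110),
                 actions=actions)
print(r.pct_reduction, r.p_administrative_new, r.minutes_saved)  # 42 0.72 13166
```

Reading the output: this seed's synthetic cohort produced 30,164 home
measurements triggering 32,216 alerts, 33% of which needed manual review;
those clustered into 4,178 e-nurse actions (77% administrative) costing
25,760 minutes over the year. The top 15% of users account for 77% of the
manual alerts. Raising the diastolic simple-alert bound from ≥105 to
≥110 mmHg would remove 42% of those alerts and save 13,166 e-nurse
minutes, while the surviving alerts skew slightly more clinical (the
administrative share drops from 0.73 to 0.72) — large burden relief, small
clinical shift.

The same pipeline is available from the shell:

```bash
telealert run-all --seed 1 --out out/
telealert simulate --config config.yaml --out out/
telealert detect out/measurements.csv --out out/
```

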