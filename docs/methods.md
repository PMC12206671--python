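# Methods

`telealert` models the alert economy of a care-path-embedded home
blood-pressure telemonitoring program: how scheduled home measurements turn
into alerts, how alerts turn into e-nurse work, and what raising
simple-alert thresholds would do to that work. This note records the model,
its assumptions, the defaults and why, and what the synthetic cohort does
and does not emulate.

## Protocol ladder and switching

Each user sits on one rung of a five-rung ladder of measurement
algorithms: four acute rungs with targets 180/110, 170/105, 160/100 and
150/95 mmHg, and one chronic rung at 140/90 mmHg. During a measurement week
the user takes four readings per day (two morning, two evening). Acute
rungs schedule measurement weeks weekly (levels 4–3) or biweekly (levels
2–1); the chronic rung schedules one week per 28 days. A measurement week
occupies the first seven days of each interval, counted from enrollment.

The two intermediate acute targets are interpolated on a uniform grid
between the published extremes (180/110 and 150/95); all five targets and
cadences are config-overridable, since programs differ.

Switching is evaluated once per measurement week. Under the default
`mean` rule a week is *on target* when the mean systolic and mean diastolic
of the taken readings are both strictly below the rung's targets (targets
are exclusive upper bounds; this matches the alerting convention, where a
reading *at* the bound is off target). An on-target week steps the user
down one rung; an off-target week leaves the rung unchanged. Escalation
(stepping back toward acute) exists but defaults off: automatic
de-escalation is the only switching direction the program description
demonstrates, and re-escalation is plausibly a clinician decision.
Alternative week rules (`all`, `majority`) are selectable. A week with
fewer than two taken readings is indeterminate: no switch, and the gap is
left to inactivity detection. One reading was judged too little evidence to
re-tier a patient (and an "on-target week" event built on a single reading
would be degenerate); the floor of two is configurable.

## Synthetic cohort

The generator emulates the aggregate structure of a one-year, 174-user
hypertension telemonitoring population (~207 active days per user, ~30,000
measurements, 45% enrolling directly into the chronic rung, and a small
subgroup concentrating most of the manual alert burden). No deposited data
exist, so calibration targets are aggregate counts, not distributions.

Per-user parameters:

* **True means.** A two-component mixture: background users draw SBP/DBP/HR
  means from N(142, 10²)/N(88, 7²)/N(72, 8²); an elevated subgroup (15% of
  users) gets +25/+15 mmHg on SBP/DBP. A single Gaussian cannot make 15% of
  users generate more than half the manual alerts; the mixture can.
  Within-user reading noise is N(0, 10²)/N(0, 6²)/N(0, 5²). Readings are
  rounded to integer mmHg/bpm, with a 10 mmHg pulse-pressure floor keeping
  SBP > DBP.
* **Active span.** Uniform on {49, …, 365} days — symmetric around the
  207-day mean within the 365-day window — with enrollment uniform over the
  dates that let the span fit (staggered/rolling enrollment).
* **Start rung.** Chronic with probability 0.45, otherwise uniform over the
  four acute rungs.
* **Adherence.** Per-user slot-taking probability ~ Beta(6, 4) (mean 0.60,
  sd 0.15). This is the one distribution calibrated to the measurement
  volume: with static true means (below), roughly 295 slots are scheduled
  per user, and 174 × 295 × 0.60 ≈ 30,800 taken measurements, matching the
  study-scale volume. An `adherence_fixed` override supports degenerate
  cohorts (full or zero adherence) for testing.
* **Dropout.** 8% of users stop measuring at a uniform point in the middle
  60% of their span, creating the inactivity cases; their scheduled slots
  remain (and go missed).

Simulation walks each user week-by-week: schedule the current rung's
slots, flip a Bernoulli per slot, draw vitals for taken slots, evaluate the
week, maybe step down, advance by the rung's interval. All randomness flows
through one seeded NumPy generator; identical config ⇒ byte-identical logs.

**What the generator does not emulate.** True means are static: there is no
treatment response, circadian structure, or drug titration (out of scope).
Two visible consequences: (1) users whose means sit above their rung's
targets never improve, so they hold dense acute schedules indefinitely —
this is why adherence, not schedule volume, carries the calibration; (2)
the elevated subgroup alerts at a higher per-measurement rate than the real
top users did, so the manual share of all alerts runs ≈33% here versus 21%
in the real program, and the subgroup's share of simple alerts overshoots
the real 61%. Passing calibration therefore shows the pipeline arithmetic
and concentration *mechanics* are right at realistic scale — not that the
generator reproduces the real program's full alert mix.

## Alert engine

Three detector families over the scheduled-slot log (one row per scheduled
slot, taken or missed):

* **Simple**: per taken reading, one alert per violated bound. High bounds
  inclusive (≥), low bounds inclusive (≤). Defaults: SBP ≥170 / ≤90, DBP
  ≥105 / ≤50, HR ≥110 / ≤45. The two high BP bounds are the program's
  published values; the low/HR bounds are invented safety-net defaults and
  nothing downstream of the headline arithmetic depends on them. Each
  simple alert records its *excess* (mmHg/bpm beyond the bound), used later
  as the classification covariate.
* **Complex**: `complex_off_target` fires once per maximal run of ≥ k
  consecutive taken readings at-or-above the rung's target (k = 4, one full
  measurement day), triggered at the k-th reading, sourcing the whole run
  — one alert per clinical episode, not per sample. Runs are not broken by
  missed slots (consecutive *taken* readings) but are broken at protocol
  switches, since "off target" is only meaningful against one target pair.
  `complex_on_target_switch` fires at the end of each on-target measurement
  week — the event driving automatic de-escalation and on-target feedback.
* **Missed**: one `overdue` alert per missed scheduled slot; one `inactive`
  alert per maximal run of ≥ x consecutive all-missed measurement-week days
  (x = 7 by default; the window length is symbolic in the program
  description and configurable here).

Routing is a total map from alert type to `auto`/`manual`. Default: overdue
and on-target-switch alerts auto (platform workflows); simple, off-target
complex and inactive alerts manual (e-nurse review). Auto + manual = total
by construction, checked.

If an externally supplied log lacks the `protocol_level` column the engine
holds each user's start rung fixed (or chronic when no user table is
given); the generator always writes the column, keeping engine and
simulation consistent.

## Workflow model

Manual alerts are clustered into one *telemonitoring action* per (user,
processing day); Saturday/Sunday alerts are folded into the following
Monday, so no action lands on a weekend. Holidays are ignored — only
weekends are described as consolidated.

Classification is a seeded stochastic stand-in for a human judgment:
administrative with probability 0.77, else clinical with subtype
probabilities 0.40 / 0.28 / 0.28 / 0.04 (phone, phone+adjustment, message,
message+adjustment). A covariate hook (default on) shifts each action's
clinical log-odds by 0.05 per mmHg of its members' maximum excess relative
to the cohort mean; the intercept is then solved by bisection so the
cohort-mean clinical probability equals the configured marginal exactly
(mean-centring alone leaves a Jensen bias, the sigmoid being convex below
½). The slope is deliberately mild: strong enough that high-excess
survivors of a threshold increase skew clinical — the qualitative shift the
scenario analysis must reproduce — without distorting the marginal.

Workload: 5 minutes per administrative and 10 per clinical action.
Count-mode workload sums exact counts. Proportion-mode workload —
`round_half_up(n·p·5 + n·(1−p)·10)` with p carried at two decimals — is
the scenario-projection arithmetic; the two modes agree to within one
clinical-action cost for any input.

All reported integers (percentages, minutes, per-user rates) use a single
round-half-up applied once to the unrounded ratio; chained rounding is
never used. Two printed study percentages (7% for 277/3646 and 28% for
130/475) are not reproducible under *any* single rounding of the printed
counts; this package reports 8 and 27 for those cells.

## Scenario analysis

A scenario raises one simple-alert bound and asks what survives. Survival
is decided on the absolute values of the original readings — an alert of
the scenario type survives iff its source reading meets the new bound; no
re-simulation (a from-scratch engine rerun at the new threshold exists
only as a test oracle, and the two paths are asserted equal on small
cohorts). The administrative share among survivors is recomputed
empirically from their action labels (two-decimal carry); when labels are
absent the current share is carried unchanged, and the mode is recorded.
Savings = proportion-mode baseline cost − proportion-mode survivor cost.

Survivor counts are defined as current − removed. The published scenario
table is internally inconsistent on this point (its post-adjustment counts
sum to the *removed* total), and its printed savings differ by ≤2 minutes
from the arithmetic above (e.g. 2994 here vs 2993 printed for the +5 mmHg
diastolic row) — consistent with undocumented intermediate rounding. Only
the two baseline workloads (6598 and 5631 minutes) are treated as exact;
per-row savings are covered by sign and monotonicity properties instead.

## Numerical and design choices

* Alert, action and measurement IDs are deterministic strings
  (`user:date:type:ordinal`), so diffs between runs are meaningful.
* Dates are timezone-free ISO-8601 calendar dates; weekdays per ISO
  (Monday = 0 in pandas terms internally).
* Concentration ranks users descending by the chosen burden metric
  (manual alerts by default), ties broken by user id; the top ⌈f·n⌉ users'
  share of each metric is reported. Share(f) ≥ f whenever ranking and
  shared metric coincide.
* Zero denominators yield `None` percentages ("undefined"), never
  exceptions.
* Problem sizes in the shipped tests: the stochastic calibration suite
  runs the full default cohort (174 users, 365-day window) over 20 seeds;
  structural and oracle tests use 15-user half-year cohorts, where
  brute-force scans are feasible.

## Known limitations

* No physiology: static means, i.i.d. noise, no treatment effect — the
  alert *mix* (manual share, simple-alert volume) deviates from the real
  program as described above.
* Action classification is exchangeable given the excess covariate; real
  e-nurse decisions surely depend on history and context.
* The inactivity window and the complex-rule variant combining several
  vitals (implemented as an optional conjunctive rule, default off) are
  program-configurable unknowns.
* The per-user-per-month workload average is not computed: its published
  denominator is ambiguous (calendar months vs months of participation).
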