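"""Configuration, file I/O and the end-to-end pipeline driver.

All artifacts are plain text: CSV logs (comma, UTF-8, header, ISO-8601
dates) and JSON summaries.  The pipeline runs simulate -> detect -> route
-> cluster -> classify -> summarize -> scenario and stamps every run with
the seed and a hash of the canonical config, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from ._common import ConfigurationError, DataError
from .alerts import ALERT_COLUMNS, AlertThresholds, RoutingPolicy, default_policy, run_engine
from .analytics import concentration, summarize_actions, summarize_alerts
from .cohort import MEASUREMENT_COLUMNS, CohortConfig, calibration_report, generate_cohort
from .protocols import ProtocolLadder, build_default_ladder
from .scenario import ScenarioSpec, scenario_table
from .workflow import ActionClassModel, WorkloadModel, classify_actions, cluster_actions, compute_workload

logger = logging.getLogger("telealert")

REQUIRED_LOG_COLUMNS = ["user_id", "date", "slot", "sbp", "dbp", "hr", "taken"]

#: The six printed scenario specs: diastolic bound raised by 5/10/15 mmHg,
#: systolic by 10/20/30.
DEFAULT_SCENARIOS = [
    ScenarioSpec("simple_dbp_high", 105, 110),
    ScenarioSpec("simple_dbp_high", 105, 115),
    ScenarioSpec("simple_dbp_high", 105, 120),
    ScenarioSpec("simple_sbp_high", 170, 180),
    ScenarioSpec("simple_sbp_high", 170, 190),
    ScenarioSpec("simple_sbp_high", 170, 200),
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs, with validated sub-configs."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    ladder: ProtocolLadder = field(default_factory=build_default_ladder)
    thresholds: AlertThresholds = field(default_factory=AlertThresholds)
    routing: dict = field(default_factory=lambda: dict(default_policy()))
    action_model: ActionClassModel = field(default_factory=ActionClassModel)
    workload: WorkloadModel = field(default_factory=WorkloadModel)
    scenarios: tuple = tuple(DEFAULT_SCENARIOS)
    out_dir: str = "telealert-out"
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(
            self,
            seed=seed,
            cohort=replace(self.cohort, seed=seed),
            action_model=replace(self.action_model, seed=seed + 1),
        )

    def to_dict(self) -> dict:
        return {
            "cohort": {
                **{
                    k: (v.isoformat() if isinstance(v, date) else v)
                    for k, v in dataclasses.asdict(self.cohort).items()
                }
            },
            "ladder": self.ladder.to_records(),
            "thresholds": dataclasses.asdict(self.thresholds),
            "routing": dict(self.routing),
            "action_model": dataclasses.asdict(self.action_model),
            "workload": dataclasses.asdict(self.workload),
            "scenarios": [dataclasses.asdict(s) for s in self.scenarios],
            "out_dir": self.out_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            cohort_d = dict(d.get("cohort", {}))
            for key in ("study_start", "study_end"):
                if key in cohort_d and isinstance(cohort_d[key], str):
                    cohort_d[key] = date.fromisoformat(cohort_d[key])
            if "adherence_beta" in cohort_d:
                cohort_d["adherence_beta"] = tuple(cohort_d["adherence_beta"])
            for key in ("user_mean_sbp_dist", "user_mean_dbp_dist", "user_mean_hr_dist"):
                if key in cohort_d:
                    cohort_d[key] = tuple(cohort_d[key])
            am = dict(d.get("action_model", {}))
            if "clinical_subtype_probs" in am:
                am["clinical_subtype_probs"] = tuple(am["clinical_subtype_probs"])
            return cls(
                cohort=CohortConfig(**cohort_d),
                ladder=(
                    ProtocolLadder.from_records(d["ladder"])
                    if "ladder" in d
                    else build_default_ladder()
                ),
                thresholds=AlertThresholds(**d.get("thresholds", {})),
                routing=dict(d.get("routing", default_policy())),
                action_model=ActionClassModel(**am),
                workload=WorkloadModel(**d.get("workload", {})),
                scenarios=tuple(
                    ScenarioSpec(**s) for s in d.get(
                        "scenarios", [dataclasses.asdict(s) for s in DEFAULT_SCENARIOS]
                    )
                ),
                out_dir=d.get("out_dir", "telealert-out"),
                seed=int(d.get("seed", 0)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError("config", str(exc)) from exc

    def config_hash(self) -> str:
        # out_dir is a run location, not scientific content
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config", "top level must be a mapping")
    return PipelineConfig.from_dict(data)


@dataclass
class RowErrorReport:
    """Malformed rows collected while reading a log (1-based line numbers)."""

    errors: list = field(default_factory=list)

    def add(self, line: int, message: str) -> None:
        self.errors.append({"line": line, "message": message})

    def __len__(self) -> int:
        return len(self.errors)


def read_measurement_log(path) -> tuple[pd.DataFrame, RowErrorReport]:
    """Read a measurement-log CSV, validating schema and row invariants.

    Missing columns raise :class:`DataError`; malformed rows (bad dates,
    vitals on missed slots, non-positive or inverted pressures) are dropped
    and reported with their line numbers.
    """
    df = pd.read_csv(path, dtype={"user_id": str, "slot": str})
    missing = [c for c in REQUIRED_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"measurement log missing columns: {missing}")
    report = RowErrorReport()
    # header is line 1 -> data row i sits on line i + 2
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    taken = df["taken"].map(
        {True: True, False: False, "True": True, "False": False, "true": True, "false": False}
    )
    keep = pd.Series(True, index=df.index)
    for i in df.index:
        line = i + 2
        if pd.isna(dates[i]):
            report.add(line, f"unparseable ISO date {df.at[i, 'date']!r}")
            keep[i] = False
            continue
        if pd.isna(taken[i]):
            report.add(line, f"unparseable taken flag {df.at[i, 'taken']!r}")
            keep[i] = False
            continue
        vitals = [df.at[i, "sbp"], df.at[i, "dbp"], df.at[i, "hr"]]
        has_vitals = [pd.notna(v) for v in vitals]
        if taken[i]:
            if not all(has_vitals):
                report.add(line, "taken row missing vitals")
                keep[i] = False
            elif not (vitals[0] > vitals[1] > 0 and vitals[2] > 0):
                report.add(line, "vitals must be positive with sbp > dbp")
                keep[i] = False
        elif any(has_vitals):
            report.add(line, "missed slot must not carry vitals")
            keep[i] = False
    out = df[keep].copy()
    out["date"] = dates[keep]
    out["taken"] = taken[keep].astype(bool)
    for col in ("sbp", "dbp", "hr"):
        out[col] = out[col].astype("Float64")
    if "measurement_id" not in out.columns:
        out["measurement_id"] = (
            out["user_id"] + ":" + out["date"].dt.strftime("%Y-%m-%d") + ":" + out["slot"]
        )
    return out.reset_index(drop=True), report


def write_measurement_log(log: pd.DataFrame, path) -> None:
    out = log.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    cols = [c for c in MEASUREMENT_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)


def write_alert_log(alerts: pd.DataFrame, path) -> None:
    out = alerts.copy()
    out["trigger_date"] = pd.to_datetime(out["trigger_date"]).dt.strftime("%Y-%m-%d")
    out["source_measurement_ids"] = out["source_measurement_ids"].map(";".join)
    out[ALERT_COLUMNS].to_csv(path, index=False)


def read_alert_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str}, keep_default_na=False, na_values=[""])
    df["trigger_date"] = pd.to_datetime(df["trigger_date"])
    df["source_measurement_ids"] = df["source_measurement_ids"].map(
        lambda s: tuple(s.split(";")) if isinstance(s, str) and s else ()
    )
    return df


def write_actions(actions: pd.DataFrame, workload: WorkloadModel, path) -> None:
    out = actions.copy()
    out["processing_date"] = pd.to_datetime(out["processing_date"]).dt.strftime("%Y-%m-%d")
    out["member_alert_ids"] = out["member_alert_ids"].map(";".join)
    minutes = {
        "administrative": workload.minutes_administrative,
        "clinical": workload.minutes_clinical,
    }
    out["minutes"] = out["action_class"].map(minutes)
    cols = [
        "action_id", "user_id", "processing_date", "n_alerts",
        "action_class", "clinical_subtype", "minutes", "member_alert_ids",
    ]
    out[cols].to_csv(path, index=False)


def read_actions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str})
    df["processing_date"] = pd.to_datetime(df["processing_date"])
    df["member_alert_ids"] = df["member_alert_ids"].map(
        lambda s: tuple(s.split(";")) if isinstance(s, str) and s else ()
    )
    return df


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all artifacts under out_dir.

    Stages: simulate -> detect+route -> cluster -> classify -> summarize ->
    scenario.  Returns {artifact name: path}.  With an empty scenario list
    the pipeline stops after the summaries.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage = "simulate"
    try:
        users, log = generate_cohort(config.cohort, config.ladder)
        logger.info("simulate: %d users, %d scheduled slots, %d taken",
                    len(users), len(log), int(log["taken"].sum()))
        stage = "detect"
        alerts = run_engine(log, users, config.ladder, config.thresholds,
                            RoutingPolicy(config.routing))
        manual = alerts[alerts["routing"] == "manual"]
        logger.info("detect: %d alerts (%d manual)", len(alerts), len(manual))
        stage = "actions"
        actions = cluster_actions(manual)
        actions = classify_actions(actions, config.action_model)
        logger.info("actions: %d actions", len(actions))
        stage = "report"
        alert_summary = summarize_alerts(
            log, alerts, n_users=len(users),
            mean_active_days=float(users["active_days"].mean()),
        )
        action_summary = summarize_actions(actions)
        conc = concentration(alerts, actions, user_ids=list(users["user_id"]))
        workload = compute_workload(actions, config.workload)
        calib = calibration_report(users, log, config.cohort)

        users_out = users.copy()
        for col in ("enrollment_date", "dropout_date"):
            users_out[col] = pd.to_datetime(users_out[col]).dt.strftime("%Y-%m-%d")
        paths["users"] = out_dir / "users.csv"
        users_out.to_csv(paths["users"], index=False)
        paths["measurements"] = out_dir / "measurements.csv"
        write_measurement_log(log, paths["measurements"])
        paths["alerts"] = out_dir / "alerts.csv"
        write_alert_log(alerts, paths["alerts"])
        paths["actions"] = out_dir / "actions.csv"
        write_actions(actions, config.workload, paths["actions"])
        paths["summary"] = out_dir / "summary.json"
        summary_payload = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "alert_summary": alert_summary.to_dict(),
            "action_summary": action_summary.to_dict(),
            "workload": dataclasses.asdict(workload),
            "total_minutes": workload.total_minutes,
            "concentration": {
                "top_fraction": conc.top_fraction,
                "n_top": conc.n_top,
                "shares": conc.shares,
            },
            "calibration": calib,
        }
        with open(paths["summary"], "w") as fh:
            json.dump(summary_payload, fh, indent=2, sort_keys=True)

        if config.scenarios:
            stage = "scenario"
            table = scenario_table(
                config.scenarios, alerts, log, actions=actions, workload=config.workload
            )
            paths["scenario_table"] = out_dir / "scenario_table.csv"
            table.to_csv(paths["scenario_table"], index=False)
            logger.info("scenario: %d rows", len(table))

        stage = "manifest"
        paths["manifest"] = out_dir / "run_manifest.json"
        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "artifacts": {k: p.name for k, p in paths.items() if k != "manifest"},
        }
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    except Exception as exc:
        # remove partial artifacts so a failed run leaves no ambiguity
        for p in paths.values():
            Path(p).unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc
    return {k: str(p) for k, p in paths.items()}


class PipelineError(DataError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
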