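"""One-command orchestration from raw signals or a metric table to the report.

Two entry modes: ``signals`` runs the full chain (preprocess, embed,
divergence, slope fits) per subject and then the cohort statistics;
``cohort-table`` consumes a per-subject metric table directly (the form the
study's deposited results take) and runs only the statistics.  Every output
carries the configuration echo and seed for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import AccelRecording, CohortTable, TurnAnnotation, read_accel, read_cohort, write_report
from .lyapunov import LdsConfig, LyapunovError, lds_pipeline
from .stats import DEFAULT_PREDICTORS, reproduce_tables

log = logging.getLogger("gaitlds")


class PipelineError(ValueError):
    pass


@dataclass
class RunConfig:
    mode: str = "cohort-table"  # "signals" | "cohort-table"
    cohort_table: str | None = None  # path, cohort-table mode
    signals_manifest: str | None = None  # path to YAML manifest, signals mode
    out_dir: str = "gaitlds_out"
    compare: tuple[str, str] = ("N", "F2+")
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    lds: LdsConfig = field(default_factory=LdsConfig)
    sensors: tuple[str, ...] = ("trunk_L5", "shank_left", "shank_right")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        lds = LdsConfig(**raw.pop("lds", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(lds=lds, **raw)
        for key in ("compare", "predictors", "sensors"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def validate(self) -> None:
        if self.mode not in ("signals", "cohort-table"):
            raise PipelineError(f"unknown mode '{self.mode}'")
        if self.mode == "cohort-table" and not self.cohort_table:
            raise PipelineError("cohort-table mode requires 'cohort_table'")
        if self.mode == "signals" and not self.signals_manifest:
            raise PipelineError("signals mode requires 'signals_manifest'")


def analyze_subject(
    recordings: dict[str, AccelRecording],
    config: LdsConfig,
    turns: TurnAnnotation | None = None,
) -> dict:
    """Per-subject metric row from in-memory recordings."""
    out = lds_pipeline(recordings, config, turns=turns)
    row: dict = {"stride_frequency": out["stride_frequency"]}
    for (sensor, axis), res in out["lyapunov"].items():
        key = "trunk" if sensor.startswith("trunk") else sensor
        row[f"stle_{key}_{axis}"] = res.stle
        row[f"ltle_{key}_{axis}"] = res.ltle
    return row


def run_signals_cohort(
    subjects: dict[str, dict[str, AccelRecording]],
    clinical: pd.DataFrame,
    lds_config: LdsConfig = LdsConfig(),
    turns: dict[str, TurnAnnotation] | None = None,
    compare: tuple[str, str] = ("N", "F2+"),
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> dict:
    """Signals-mode cohort analysis over in-memory per-subject recordings.

    ``clinical`` carries one row per subject_id with the non-signal fields
    (Tinetti scores, prospective falls, demographics).  Failing subjects are
    reported, not fatal.
    """
    rows = []
    failures = {}
    for sid, recs in subjects.items():
        try:
            row = analyze_subject(recs, lds_config, turns=(turns or {}).get(sid))
        except LyapunovError as exc:
            failures[sid] = str(exc)
            log.warning("subject %s failed: %s", sid, exc)
            continue
        row["subject_id"] = sid
        rows.append(row)
    if not rows:
        raise PipelineError("all subjects failed signal analysis")
    metrics = pd.DataFrame(rows)
    merged = clinical.merge(metrics, on="subject_id", how="inner",
                            suffixes=("_clinical", ""))
    cohort = CohortTable(merged)
    sizes = cohort.group_sizes
    results: dict = {"subjects": cohort.data, "failures": failures,
                     "group_sizes": sizes}
    if min(sizes.get(g, 0) for g in compare) < 3:
        results["warnings"] = [
            f"comparison {compare} skipped: groups too small ({sizes})"]
    else:
        results["tables"] = reproduce_tables(cohort, compare=compare,
                                             predictors=predictors)
    return results


def _load_manifest(path: str | Path) -> tuple[dict, pd.DataFrame, dict]:
    """Manifest YAML: cohort_table path + per-subject sensor file map."""
    raw = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    clinical = read_cohort(base / raw["cohort_table"]).data
    subjects: dict[str, dict[str, AccelRecording]] = {}
    turns: dict[str, TurnAnnotation] = {}
    for sid, entry in raw["subjects"].items():
        recs = {}
        for sensor, fname in entry["sensors"].items():
            recs[sensor] = read_accel(base / fname, sensor_id=sensor,
                                      column_map=entry.get("column_map"))
        subjects[str(sid)] = recs
        if "turns" in entry:
            turns[str(sid)] = TurnAnnotation(
                intervals=[tuple(iv) for iv in entry["turns"]])
    return subjects, clinical, turns


def run(config: RunConfig) -> dict:
    """Execute a configured run and write the report bundle."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.mode == "cohort-table":
        cohort = read_cohort(config.cohort_table)
        results: dict = {
            "subjects": cohort.data,
            "group_sizes": cohort.group_sizes,
            "tables": reproduce_tables(cohort, compare=config.compare,
                                       predictors=config.predictors),
        }
        if cohort.validation_errors:
            results["validation_errors"] = cohort.validation_errors
    else:
        subjects, clinical, turns = _load_manifest(config.signals_manifest)
        subjects = {
            sid: {s: r for s, r in recs.items() if s in config.sensors}
            for sid, recs in subjects.items()
        }
        results = run_signals_cohort(subjects, clinical, config.lds,
                                     turns=turns, compare=config.compare,
                                     predictors=config.predictors)
    results["provenance"] = {
        "package": "gaitlds",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(_config_dict(config), default=str)),
    }
    write_report(results, out_dir)
    log.info("report written to %s", out_dir)
    return results


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d
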