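"""Readers, writers and validated containers for signals and cohort tables.

Accelerometer recordings are plain delimited text (CSV/TSV) with a header row
naming a time column and the three anatomical axes (anterior-posterior,
vertical, medial-lateral).  Cohort tables carry one row per subject with
clinical scores (Tinetti balance/gait/total), gait metrics and prospective
fall counts; the fall group (N / F1 / F2+) is always derived from the count,
never trusted from the file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

SENSORS = ("trunk_L5", "shank_left", "shank_right")
AXES = ("ap", "v", "ml")
GROUP_LABELS = ("N", "F1", "F2+")

#: per sensor x axis local-dynamic-stability column names used in cohort tables
STLE_COLUMNS = tuple(f"stle_{s}_{a}" for s in ("trunk", "shank_left", "shank_right") for a in AXES)
LTLE_COLUMNS = tuple(f"ltle_{s}_{a}" for s in ("trunk", "shank_left", "shank_right") for a in AXES)


class GaitIOError(ValueError):
    """Raised for malformed input files or invalid container contents."""


@dataclass
class AccelRecording:
    """Tri-axial acceleration from one body-fixed sensor.

    Attributes
    ----------
    sensor_id : one of ``trunk_L5``, ``shank_left``, ``shank_right`` (free
        labels are accepted but the pipeline keys embedding defaults off the
        ``trunk``/``shank`` prefix).
    fs : sampling rate in Hz.
    t : sample times in seconds, strictly increasing, spacing ~ 1/fs.
    a_ap, a_v, a_ml : acceleration in m s^-2 along the anterior-posterior,
        vertical and medial-lateral axes.
    """

    sensor_id: str
    fs: float
    t: np.ndarray
    a_ap: np.ndarray
    a_v: np.ndarray
    a_ml: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a_ap = np.asarray(self.a_ap, dtype=float)
        self.a_v = np.asarray(self.a_v, dtype=float)
        self.a_ml = np.asarray(self.a_ml, dtype=float)
        n = self.t.size
        if n < 2:
            raise GaitIOError(f"recording '{self.sensor_id}': need >= 2 samples, got {n}")
        for name in ("a_ap", "a_v", "a_ml"):
            if getattr(self, name).size != n:
                raise GaitIOError(
                    f"recording '{self.sensor_id}': column '{name}' length "
                    f"{getattr(self, name).size} != time length {n}"
                )
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise GaitIOError(f"recording '{self.sensor_id}': fs must be > 0, got {self.fs}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise GaitIOError(f"recording '{self.sensor_id}': non-monotone time")
        jitter = np.abs(dt * self.fs - 1.0)
        if jitter.max() > 0.01:
            raise GaitIOError(
                f"recording '{self.sensor_id}': sample spacing inconsistent with "
                f"fs={self.fs} Hz (relative jitter {jitter.max():.3g} > 1%)"
            )

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def axis(self, name: str) -> np.ndarray:
        if name not in AXES:
            raise GaitIOError(f"unknown axis '{name}', expected one of {AXES}")
        return getattr(self, f"a_{name}")


@dataclass
class TurnAnnotation:
    """Externally marked U-turn intervals, as (start_s, end_s) times."""

    intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        iv = [(float(a), float(b)) for a, b in self.intervals]
        for a, b in iv:
            if b <= a:
                raise GaitIOError(f"turn interval ({a}, {b}) has non-positive length")
        for (a0, b0), (a1, b1) in zip(iv, iv[1:]):
            if a1 < b0:
                raise GaitIOError("turn intervals overlap or are unordered")
        self.intervals = iv


def derive_group(prospective_falls: int) -> str:
    """N for 0 included falls, F1 for exactly one, F2+ for two or more."""
    if prospective_falls < 0:
        raise GaitIOError(f"negative fall count {prospective_falls}")
    if prospective_falls == 0:
        return "N"
    if prospective_falls == 1:
        return "F1"
    return "F2+"


_COUNT_COLS = ("baseline_falls", "prospective_falls")
_TINETTI_COLS = ("tinetti_balance", "tinetti_gait", "tinetti_total")


def validate_cohort_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Validate per-subject rows; return the clean frame and per-row error report.

    Rows missing the group-defining fall count, with negative counts or with
    non-integer Tinetti scores are dropped and reported.  The ``group`` column
    is (re)derived from ``prospective_falls``.
    """
    errors: list[str] = []
    df = df.copy().reset_index(drop=True)
    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(len(df))])
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        sid = row["subject_id"]
        falls = row.get("prospective_falls", np.nan)
        if pd.isna(falls):
            errors.append(f"{sid}: missing prospective_falls (group undefined)")
            keep[i] = False
            continue
        for col in _COUNT_COLS:
            v = row.get(col, np.nan)
            if not pd.isna(v) and v < 0:
                errors.append(f"{sid}: negative count in '{col}' ({v})")
                keep[i] = False
        for col in _TINETTI_COLS:
            v = row.get(col, np.nan)
            if not pd.isna(v) and float(v) != int(v):
                errors.append(f"{sid}: non-integer Tinetti score in '{col}' ({v})")
                keep[i] = False
        b, g, tot = (row.get(c, np.nan) for c in _TINETTI_COLS)
        if not any(pd.isna(v) for v in (b, g, tot)) and b + g != tot:
            errors.append(f"{sid}: tinetti_total {tot} != balance {b} + gait {g}")
            keep[i] = False
    clean = df.loc[keep].reset_index(drop=True)
    clean["group"] = [derive_group(int(v)) for v in clean["prospective_falls"]]
    return clean, errors


@dataclass
class CohortTable:
    """Per-subject predictors plus the prospective fall group label.

    Thin validated wrapper over a :class:`pandas.DataFrame`; the frame is the
    working surface, the wrapper enforces the N/F1/F2+ derivation rule.
    """

    data: pd.DataFrame
    validation_errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        clean, errors = validate_cohort_frame(self.data)
        self.data = clean
        self.validation_errors = list(self.validation_errors) + errors

    def __len__(self) -> int:
        return len(self.data)

    @property
    def group_sizes(self) -> dict[str, int]:
        counts = self.data["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUP_LABELS}

    def group(self, label: str) -> pd.DataFrame:
        return self.data[self.data["group"] == label]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path, sep=None, engine="python")


def read_accel(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    fs: float | None = None,
    sensor_id: str = "trunk_L5",
) -> AccelRecording:
    """Read one sensor's recording from delimited text.

    ``column_map`` maps the canonical names ``time``/``ap``/``v``/``ml`` to
    the file's header names (defaults to identical names).  ``fs`` is
    inferred from the median sample spacing when not given; a provided value
    must agree with the data within 1%.
    """
    path = Path(path)
    cmap = dict(column_map or {})
    for key in ("time", "ap", "v", "ml"):
        cmap.setdefault(key, key)
    df = _read_delimited(path)
    for key, col in cmap.items():
        if col not in df.columns:
            raise GaitIOError(f"{path.name}: missing column '{col}' (for '{key}')")
    t = df[cmap["time"]].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise GaitIOError(f"{path.name}: non-monotone time in column '{cmap['time']}'")
    fs_data = 1.0 / float(np.median(np.diff(t)))
    if fs is None:
        fs = fs_data
    elif abs(fs_data / fs - 1.0) > 0.01:
        raise GaitIOError(
            f"{path.name}: fs={fs} Hz disagrees with median sample spacing "
            f"({fs_data:.4g} Hz) by more than 1%"
        )
    return AccelRecording(
        sensor_id=sensor_id,
        fs=float(fs),
        t=t,
        a_ap=df[cmap["ap"]].to_numpy(dtype=float),
        a_v=df[cmap["v"]].to_numpy(dtype=float),
        a_ml=df[cmap["ml"]].to_numpy(dtype=float),
    )


def write_accel(rec: AccelRecording, path: str | Path) -> Path:
    """Write a recording as CSV with full float precision (1e-9 round-trip)."""
    path = Path(path)
    df = pd.DataFrame({"time": rec.t, "ap": rec.a_ap, "v": rec.a_v, "ml": rec.a_ml})
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_cohort(path: str | Path) -> CohortTable:
    """Read a per-subject cohort table (CSV/TSV/XLSX); derive fall groups.

    Invalid rows are dropped; the report is on ``CohortTable.validation_errors``.
    """
    df = _read_delimited(path)
    table = CohortTable(df)
    if table.validation_errors:
        warnings.warn(
            f"{Path(path).name}: rejected {len(table.validation_errors)} row issue(s); "
            "see CohortTable.validation_errors",
            stacklevel=2,
        )
    return table


def write_cohort(table: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False, float_format="%.12g")
    return path


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(results: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write per-subject metrics (CSV) and cohort statistics (JSON).

    ``results`` may carry a ``subjects`` DataFrame and arbitrary nested
    statistic blocks; output is bit-stable for identical inputs (sorted keys,
    fixed float formatting).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    subjects = results.get("subjects")
    sub_path = out_dir / "subjects.csv"
    if subjects is not None and len(subjects):
        pd.DataFrame(subjects).to_csv(sub_path, index=False, float_format="%.12g")
    else:
        # header-only file so downstream tooling always finds the artefact
        cols = list(subjects.columns) if isinstance(subjects, pd.DataFrame) else ["subject_id"]
        pd.DataFrame(columns=cols).to_csv(sub_path, index=False)
    written["subjects"] = sub_path
    stats = {k: v for k, v in results.items() if k != "subjects"}
    rep_path = out_dir / "report.json"
    rep_path.write_text(json.dumps(_jsonify(stats), indent=2, sort_keys=True) + "\n")
    written["report"] = rep_path
    return written
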