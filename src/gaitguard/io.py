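"""File formats: sensor CSV logs, feature matrices, histories, run configs.

Sensor logs are plain CSV with header ``t,ax,ay,az,gx,gy,gz`` (seconds, SI
units, one row per sample) plus a ``<stem>.meta.json`` sidecar carrying the
subject, activity, honesty, and strategy metadata. Feature matrices are CSV
with provenance columns followed by the 260 schema-named feature columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import LabeledFrameSet, feature_schema
from .simulate import SAMPLE_RATE, SensorStream, StrategyParams

SENSOR_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")
_TIME_TOL = 1e-6  # seconds


class SensorFormatError(ValueError):
    """Raised for malformed sensor CSV files."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json")


def write_sensor_csv(stream: SensorStream, path: str | Path) -> None:
    """Write a stream as CSV plus a metadata sidecar JSON."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": stream.timestamps,
            "ax": stream.accel[:, 0],
            "ay": stream.accel[:, 1],
            "az": stream.accel[:, 2],
            "gx": stream.gyro[:, 0],
            "gy": stream.gyro[:, 1],
            "gz": stream.gyro[:, 2],
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "subject_id": stream.subject_id,
        "sample_rate": stream.sample_rate,
        "true_activity": stream.true_activity,
        "honesty": stream.honesty,
        "trial_id": stream.trial_id,
        "strategy": stream.strategy.to_dict() if stream.strategy else None,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_sensor_csv(path: str | Path) -> SensorStream:
    """Read a sensor CSV (columns matched by name) and its sidecar.

    Raises :class:`SensorFormatError` naming the first offending row for
    missing columns, non-numeric cells, or non-uniform timestamps (tolerance
    1e-6 s).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise SensorFormatError(f"{path}: missing columns {missing}")
    for col in SENSOR_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        nan_rows = np.flatnonzero(df[col].isna().to_numpy())
        first_bad = min(
            [int(b) for b in bad] + [int(b) for b in nan_rows], default=None
        )
        if first_bad is not None:
            raise SensorFormatError(
                f"{path}: non-numeric value in column {col!r} at data row {first_bad}"
            )
        df[col] = vals

    meta_path = _sidecar(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    t = df["t"].to_numpy(float)
    rate = float(meta.get("sample_rate", SAMPLE_RATE))
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.flatnonzero(np.abs(dt - 1.0 / rate) > _TIME_TOL)
        if bad.size:
            raise SensorFormatError(
                f"{path}: non-uniform timestamp at data row {int(bad[0]) + 1} "
                f"(dt={dt[bad[0]]:.6g}, expected {1.0 / rate:.6g})"
            )
    strategy = meta.get("strategy")
    return SensorStream(
        subject_id=str(meta.get("subject_id", path.stem)),
        timestamps=t,
        accel=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        true_activity=meta.get("true_activity", "sitting"),
        honesty=meta.get("honesty", "normal"),
        strategy=StrategyParams.from_dict(strategy) if strategy else None,
        sample_rate=rate,
        trial_id=meta.get("trial_id"),
    )


PROVENANCE_COLUMNS = ("subject_id", "trial_id", "frame_start", "label", "honesty")


def write_frameset_csv(fs: LabeledFrameSet, path: str | Path) -> None:
    """Feature matrix CSV: provenance columns, then schema-named features."""
    names = feature_schema().names
    df = pd.DataFrame(fs.X, columns=list(names))
    for col, val in zip(
        PROVENANCE_COLUMNS, (fs.subject_id, fs.trial_id, fs.frame_start, fs.y, fs.honesty)
    ):
        df.insert(list(PROVENANCE_COLUMNS).index(col), col, val)
    df.to_csv(path, index=False)


def read_frameset_csv(path: str | Path) -> LabeledFrameSet:
    df = pd.read_csv(path, float_precision="round_trip")
    names = list(feature_schema().names)
    missing = [c for c in (*PROVENANCE_COLUMNS, *names) if c not in df.columns]
    if missing:
        raise SensorFormatError(f"{path}: missing columns {missing[:5]}...")
    return LabeledFrameSet(
        X=df[names].to_numpy(float),
        y=df["label"].to_numpy(object),
        honesty=df["honesty"].to_numpy(object),
        subject_id=df["subject_id"].astype(str).to_numpy(object),
        trial_id=df["trial_id"].astype(str).to_numpy(object),
        frame_start=df["frame_start"].to_numpy(int),
    )


@dataclasses.dataclass
class RunConfig:
    """One end-to-end run: cohort, experiment, and sweep settings."""

    cohort_size: int = 8
    seed: int = 0
    session_s: float = 300.0
    trial_max_duration_s: float = 300.0
    class_count_cap: int = 150
    max_rounds: int = 10
    n_trees: int = 200
    n_split_candidates: int = 16
    n_candidates: int = 20
    probe_s: float = 10.0
    sweep_repeats: int = 10
    outdir: str = "gaitguard_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def save_history(history, outdir: str | Path) -> None:
    """Persist an experiment history: JSON summary + feature CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .forest import serialize_forest

    doc = {
        "subject_id": history.subject_id,
        "terminal_reason": history.terminal_reason,
        "rounds": [
            {
                "sitting_trial": _trial_summary(r.sitting_trial),
                "walking_trial": _trial_summary(r.walking_trial),
                "retrained": r.retrained,
            }
            for r in history.rounds
        ],
    }
    (outdir / "history.json").write_text(json.dumps(doc, indent=1))
    (outdir / "model.json").write_text(serialize_forest(history.final_forest))
    write_frameset_csv(history.normal_data, outdir / "normal.csv")
    write_frameset_csv(history.deceptive_data, outdir / "deceptive.csv")
    for i, r in enumerate(history.rounds, start=1):
        for name, trial in (("sitting", r.sitting_trial), ("walking", r.walking_trial)):
            pd.DataFrame(
                {
                    "t": trial.eval_times,
                    "predicted": trial.predicted,
                    "confidence": trial.confidence,
                }
            ).to_csv(outdir / f"round{i}_{name}_log.csv", index=False)


def _trial_summary(trial) -> dict:
    return {
        "true_activity": trial.true_activity,
        "strategy": trial.strategy.to_dict(),
        "n_evaluations": trial.n_evaluations,
        "detected_counts": trial.detected_counts,
        "success_rate": trial.success_rate,
        "successful": trial.successful,
    }


def load_history_data(outdir: str | Path):
    """Reload the (normal, deceptive) framesets written by ``save_history``."""
    outdir = Path(outdir)
    return read_frameset_csv(outdir / "normal.csv"), read_frameset_csv(
        outdir / "deceptive.csv"
    )
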