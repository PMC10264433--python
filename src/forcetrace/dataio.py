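"""Reading and writing recordings, segment tables, feature tables and
run artifacts in stable text formats (CSV / JSON / YAML).

Readers validate rather than coerce: NaN forces, missing columns,
non-uniform sampling and overlapping segments are rejected with errors
naming the offending row.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ForceRecording, ForceSegment

RECORDING_COLUMNS = ("time_s", "left_force_n", "right_force_n")
SEGMENT_COLUMNS = ("segment_id", "start_idx", "end_idx", "task", "skill",
                   "surgeon_id")


class SchemaError(ValueError):
    """A file does not conform to the expected tabular schema."""


def write_recording(rec: ForceRecording, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": rec.time,
        "left_force_n": rec.left,
        "right_force_n": rec.right,
    })
    if rec.labels is not None:
        df["label"] = np.where(rec.labels, "ON", "OFF")
    df.to_csv(path, index=False)


def read_recording(path: str | Path, fs: float = 20.0) -> ForceRecording:
    df = pd.read_csv(path)
    for col in RECORDING_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in ("left_force_n", "right_force_n"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise SchemaError(f"{path}: NaN force in column {col!r} at row "
                              f"{int(bad[0])}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1:
        steps = np.diff(t)
        expected = 1.0 / fs
        off = np.abs(steps - expected) > 1e-6
        if off.any():
            row = int(np.argmax(off)) + 1
            raise SchemaError(f"{path}: non-uniform sampling at row {row} "
                              f"(step {steps[row - 1]:.6g}s, expected "
                              f"{expected:.6g}s)")
    labels = None
    if "label" in df.columns:
        vals = df["label"].astype(str)
        unknown = ~vals.isin(["ON", "OFF"])
        if unknown.any():
            row = int(np.argmax(unknown.to_numpy()))
            raise SchemaError(f"{path}: unknown label at row {row}")
        labels = (vals == "ON").to_numpy()
    return ForceRecording(left=df["left_force_n"].to_numpy(dtype=float),
                          right=df["right_force_n"].to_numpy(dtype=float),
                          fs=fs, labels=labels)


def write_segments(segments: list[ForceSegment], path: str | Path) -> None:
    df = pd.DataFrame([{
        "segment_id": seg.segment_id,
        "start_idx": seg.start,
        "end_idx": seg.end,
        "task": seg.task,
        "skill": seg.skill,
        "surgeon_id": seg.surgeon_id,
    } for seg in segments], columns=list(SEGMENT_COLUMNS))
    df.to_csv(path, index=False)


def read_segments(path: str | Path,
                  recording: ForceRecording | None = None) -> pd.DataFrame:
    """Read a segment table; returns the validated DataFrame.

    When ``recording`` is given the traces can be materialized with
    :func:`cut_segments`. Indices follow the 0-based half-open
    [start, end) convention.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        return pd.DataFrame(columns=list(SEGMENT_COLUMNS))
    for col in SEGMENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    bad = df.index[df["start_idx"] >= df["end_idx"]]
    if len(bad):
        raise SchemaError(f"{path}: start_idx >= end_idx at row {int(bad[0])}")
    ordered = df.sort_values("start_idx").reset_index(drop=True)
    overlap = ordered["start_idx"].to_numpy()[1:] < ordered["end_idx"].to_numpy()[:-1]
    if overlap.any():
        row = int(np.argmax(overlap)) + 1
        raise SchemaError(f"{path}: overlapping segments at sorted row {row}")
    if recording is not None and ordered["end_idx"].max() > len(recording):
        raise SchemaError(f"{path}: segment exceeds recording length")
    return ordered


def cut_segments(recording: ForceRecording, table: pd.DataFrame,
                 ) -> list[ForceSegment]:
    segments = []
    for _, row in table.iterrows():
        s, e = int(row["start_idx"]), int(row["end_idx"])
        segments.append(ForceSegment(
            left=recording.left[s:e], right=recording.right[s:e],
            task=row["task"], skill=row["skill"],
            surgeon_id=str(row["surgeon_id"]), fs=recording.fs,
            segment_id=int(row["segment_id"]), start=s))
    return segments


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    num = df.select_dtypes(include=[np.number])
    if num.isna().any().any():
        col = num.columns[num.isna().any()][0]
        raise SchemaError(f"{path}: NaN value in feature column {col!r}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default)
                          + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: run config must be a YAML mapping")
    return cfg


def write_run_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
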