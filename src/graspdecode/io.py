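"""Delimited-text formats for trajectories, events, ROI matrices and configs.

All core exchange formats are plain text so the pipelines have no binary
dependency:

* trajectory files: long CSV/TSV with columns
  ``time_s, marker, x_mm, y_mm, z_mm`` (markers wrist/thumb/index), one file
  per trial, plus a manifest CSV (subject, condition, trial, path);
* events tables: BIDS-style TSV with ``onset, duration, trial_type``
  (trial_type social/individual, matched case-insensitively);
* ROI matrices: delimited numeric matrix, rows = voxels, columns = volumes;
* experiment configs: one flat YAML mapping; unknown keys are errors and a
  seed is mandatory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .kinematics import MARKERS, MarkerTrajectory
from .mvpa import RoiRunSeries
from .sim_fmri import FmriSimConfig, RunEvents
from .sim_kinematics import KinSimConfig

__all__ = [
    "write_trajectory", "read_trajectory_file",
    "write_events_table", "read_events_table",
    "write_roi_matrix", "read_roi_matrix",
    "write_manifest", "read_manifest",
    "load_config",
]

_LABEL_BY_NAME = {"social": 1, "individual": -1}
_NAME_BY_LABEL = {1: "social", -1: "individual"}


def _read_delimited(path, **kw) -> pd.DataFrame:
    """Read a comma- or tab-separated table, auto-detecting the delimiter."""
    return pd.read_csv(path, sep=None, engine="python", **kw)


def write_trajectory(traj: MarkerTrajectory, path) -> None:
    frames = []
    for marker in MARKERS:
        pos = traj.marker(marker)
        frames.append(pd.DataFrame({
            "time_s": traj.time, "marker": marker,
            "x_mm": pos[:, 0], "y_mm": pos[:, 1], "z_mm": pos[:, 2],
        }))
    pd.concat(frames).to_csv(path, index=False)


def read_trajectory_file(path, meta: dict | None = None) -> MarkerTrajectory:
    """Load and validate one trial's trajectory file.

    Enforces: all three markers present with identical time grids, a uniform
    sampling grid (within 1%), numeric cells. Schema violations raise
    :class:`~graspdecode.errors.SchemaError` with offending row numbers.
    """
    df = _read_delimited(path)
    required = {"time_s", "marker", "x_mm", "y_mm", "z_mm"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    for col in ("time_s", "x_mm", "y_mm", "z_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise SchemaError(f"{path}: non-numeric {col} at rows {bad[:5]}")
        df[col] = vals
    series = {}
    time = None
    for marker in MARKERS:
        sub = df[df["marker"] == marker].sort_values("time_s")
        if sub.empty:
            raise SchemaError(f"{path}: missing marker '{marker}'")
        t = sub["time_s"].to_numpy()
        if np.any(np.diff(t) == 0):
            rows = sub.index[np.nonzero(np.diff(t) == 0)[0]].tolist()
            raise SchemaError(f"{path}: duplicated timestamps for '{marker}' "
                              f"at rows {rows[:5]}")
        if time is None:
            time = t
        elif t.shape != time.shape or not np.allclose(t, time):
            raise SchemaError(f"{path}: marker '{marker}' time grid differs")
        series[marker] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
    dt = np.diff(time)
    if np.any(np.abs(dt - np.median(dt)) > 0.01 * np.median(dt)):
        raise SchemaError(f"{path}: non-uniform sampling grid (>1% deviation)")
    return MarkerTrajectory(time=time, meta=dict(meta or {}), **series)


def write_manifest(trials: list[MarkerTrajectory], root: Path) -> pd.DataFrame:
    """Write one trajectory file per trial plus a manifest CSV under root."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for traj in trials:
        m = traj.meta
        name = f"sub-{m['subject']:02d}_{m['condition']}_trial-{m['trial']:02d}.csv"
        write_trajectory(traj, root / name)
        rows.append({"subject": m["subject"], "condition": m["condition"],
                     "trial": m["trial"], "path": name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / "manifest.csv", index=False)
    return manifest


def read_manifest(root: Path) -> list[MarkerTrajectory]:
    root = Path(root)
    manifest = _read_delimited(root / "manifest.csv")
    trials = []
    for _, row in manifest.iterrows():
        path = root / row["path"]
        if not path.exists():
            raise SchemaError(f"manifest entry {row['path']} does not exist")
        trials.append(read_trajectory_file(
            path,
            meta={"subject": int(row["subject"]), "condition": row["condition"],
                  "trial": int(row["trial"])},
        ))
    return trials


def write_events_table(events: RunEvents, path) -> None:
    pd.DataFrame({
        "onset": events.onsets,
        "duration": np.full(events.onsets.size, events.trial_duration),
        "trial_type": [_NAME_BY_LABEL[v] for v in events.labels],
    }).to_csv(path, sep="\t", index=False)


def read_events_table(path, run: int = 1) -> RunEvents:
    """Load a BIDS-style events TSV; trial_type is case-insensitive."""
    df = _read_delimited(path)
    required = {"onset", "duration", "trial_type"}
    if not required <= set(df.columns):
        raise SchemaError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    onsets = pd.to_numeric(df["onset"], errors="coerce")
    if onsets.isna().any():
        raise SchemaError(f"{path}: non-numeric onsets")
    if (onsets < 0).any():
        raise SchemaError(f"{path}: negative onset(s)")
    if not onsets.is_monotonic_increasing:
        raise SchemaError(f"{path}: onsets must be sorted")
    labels = []
    for i, val in enumerate(df["trial_type"]):
        key = str(val).strip().lower()
        if key not in _LABEL_BY_NAME:
            raise SchemaError(f"{path}: unknown trial_type {val!r} at row {i}")
        labels.append(_LABEL_BY_NAME[key])
    duration = float(df["duration"].iloc[0]) if len(df) else 0.0
    return RunEvents(run=run, onsets=onsets.to_numpy(float),
                     labels=np.array(labels), trial_duration=duration)


def write_roi_matrix(series: RoiRunSeries, path) -> None:
    np.savetxt(path, series.data, delimiter=",")


def read_roi_matrix(
    path, tr: float, roi: str = "ROI", run: int = 1,
    hemisphere: str | None = None, n_voxels: int | None = None,
) -> RoiRunSeries:
    """Load a voxel x volume matrix; optionally check the declared voxel
    count."""
    try:
        data = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if n_voxels is not None and data.shape[0] != n_voxels:
        raise SchemaError(
            f"{path}: {data.shape[0]} rows but {n_voxels} voxels declared"
        )
    return RoiRunSeries(roi=roi, run=run, data=data, tr=tr, hemisphere=hemisphere)


_CONFIG_CLASSES = {"kinematics": KinSimConfig, "fmri": FmriSimConfig}


def load_config(path, kind: str):
    """Load a flat YAML simulator config.

    ``kind`` is "kinematics" or "fmri". Unknown keys are collected into a
    single aggregated error (fail-fast); ``seed`` must be present.
    """
    cls = _CONFIG_CLASSES[kind]
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a flat mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {unknown}")
    if "seed" not in raw:
        raise SchemaError(f"{path}: 'seed' is mandatory")
    # tuples survive YAML round-trips as lists
    for key, val in raw.items():
        if isinstance(val, list):
            raw[key] = tuple(val)
    return cls(**raw)
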