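"""Trajectory CSV dialect and config I/O.

Trajectory files are tidy CSVs with header
``mouse_id,group,phase,session,trial,t_s,x_cm,y_cm``; rows are grouped by
trial with t ascending, coordinates pool-centred in cm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arena import PHASES, ArenaSpec, Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "write_trajectories",
    "read_trajectories",
    "write_table",
    "write_json",
]

TRAJECTORY_COLUMNS = ("mouse_id", "group", "phase", "session", "trial", "t_s", "x_cm", "y_cm")

_FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """A file does not match the expected tabular schema."""


def write_trajectories(trajectories: list[Trajectory], path) -> Path:
    path = Path(path)
    frames = []
    for tr in trajectories:
        frames.append(pd.DataFrame({
            "mouse_id": tr.mouse_id,
            "group": tr.group,
            "phase": tr.phase,
            "session": tr.session,
            "trial": tr.trial,
            "t_s": tr.t,
            "x_cm": tr.xy[:, 0],
            "y_cm": tr.xy[:, 1],
        }))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(TRAJECTORY_COLUMNS))
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_trajectories(path, arena: ArenaSpec, validate: bool = True) -> list[Trajectory]:
    """Read a trajectory CSV and reconstruct per-trial paths.

    A trial whose last time stamp falls short of the maximum duration is
    taken as escaped and must end on its phase's platform.  Validation
    errors report the offending mouse/trial and row numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty trajectory file") from exc
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise SchemaError(f"{path}: no trajectory rows")
    bad_phase = set(df["phase"].unique()) - set(PHASES)
    if bad_phase:
        raise ValueError(f"{path}: unknown phase labels {sorted(bad_phase)}")

    trajectories = []
    for (mouse, group, phase, session, trial), sub in df.groupby(
        ["mouse_id", "group", "phase", "session", "trial"], sort=False
    ):
        t = sub["t_s"].to_numpy(dtype=float)
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            row = sub.index[int(np.argmax(np.diff(t) <= 0)) + 1]
            raise ValueError(
                f"{path}: non-monotone t for {mouse} {phase} s{session} t{trial} (row {row + 2})"
            )
        xy = sub[["x_cm", "y_cm"]].to_numpy(dtype=float)
        r = np.hypot(xy[:, 0], xy[:, 1])
        tol = 1e-6 * max(1.0, arena.pool_radius)
        if np.any(r > arena.pool_radius + tol):
            row = sub.index[int(np.argmax(r > arena.pool_radius + tol))]
            raise ValueError(f"{path}: point outside the pool at row {row + 2}")
        escaped = bool(t[-1] < arena.max_trial_duration - arena.dt / 2) and phase != "REM"
        traj = Trajectory(
            mouse_id=str(mouse), group=str(group), phase=str(phase),
            session=int(session), trial=int(trial), t=t, xy=xy, escaped=escaped,
        )
        if validate:
            traj.validate(arena)
        trajectories.append(traj)
    return trajectories


def write_table(df: pd.DataFrame, path, schema: dict | None = None) -> Path:
    """Write a CSV with an optional sidecar JSON schema."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if schema is not None:
        write_json(schema, path.with_suffix(".schema.json"))
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
    return path


def write_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
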