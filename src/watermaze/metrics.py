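"""Per-trial behavioural variables and derived tables.

The seven variables entering all downstream statistics are, in canonical
order: escape latency, % time in target quadrant, % time in periphery
(thigmotaxis), Whishaw corridor index, Gallagher proximity index, path
length, and mean swimming speed.  Latencies censored at the trial bound
enter descriptive averages at the bound itself; only the censored
regression treats them specially.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .arena import ArenaSpec, Trajectory

__all__ = [
    "METRIC_VARIABLES",
    "TrialMetrics",
    "RecognitionResult",
    "resample_path",
    "resample_arclength",
    "compute_trial_metrics",
    "metrics_table",
    "session_average",
    "discrimination_index",
    "apply_inclusion_filters",
]

#: Canonical variable order of the session-level metric vector.  This order
#: is fixed across the whole pipeline (median matrices, PCA loadings, CSVs).
METRIC_VARIABLES = (
    "latency",
    "target_quadrant_pct",
    "thigmotaxis_pct",
    "whishaw_pct",
    "gallagher_index",
    "path_length",
    "mean_speed",
)

#: Default resampling rate (Hz) for the accumulated Gallagher distance.
GALLAGHER_RATE = 1.0

#: Default arc-length spacing (cm) of the Whishaw path resampling.
WHISHAW_SPACING = 1.0


@dataclass(frozen=True)
class TrialMetrics:
    mouse_id: str
    group: str
    phase: str
    session: int
    trial: int
    latency: float
    censored: bool
    first_entry_latency: float
    first_entry_censored: bool
    path_length: float
    mean_speed: float
    thigmotaxis_pct: float
    whishaw_pct: float
    gallagher_index: float
    gallagher_distance: float
    target_quadrant_pct: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RecognitionResult:
    """Novel-object exploration times and discrimination index (%)."""

    novel_time: float
    familiar_time: float
    di: float


def resample_path(traj: Trajectory, rate: float) -> Trajectory:
    """Linear interpolation of a path at uniform dt = 1/rate.

    The grid runs from t = 0 to the last time stamp inclusive; the final
    sample is appended when the duration is not a multiple of dt, so the
    endpoints are always preserved.  A single-sample path is returned
    unchanged with a warning.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if traj.n_samples < 2:
        warnings.warn("single-sample path left unresampled", RuntimeWarning, stacklevel=2)
        return traj
    dt = 1.0 / rate
    duration = traj.duration
    n = int(math.floor(duration / dt + 1e-9)) + 1
    grid = np.arange(n) * dt
    if duration - grid[-1] > 1e-9 * max(1.0, duration):
        grid = np.append(grid, duration)
    x = np.interp(grid, traj.t, traj.xy[:, 0])
    y = np.interp(grid, traj.t, traj.xy[:, 1])
    return replace(traj, t=grid, xy=np.column_stack([x, y]))


def resample_arclength(xy: np.ndarray, spacing: float = WHISHAW_SPACING) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing, endpoints included.

    A (near-)zero-length path collapses to its single location.
    """
    xy = np.asarray(xy, dtype=float)
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if xy.shape[0] < 2:
        return xy.copy()
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 1e-12:
        return xy[:1].copy()
    n = int(math.floor(total / spacing + 1e-9)) + 1
    grid = np.arange(n) * spacing
    if total - grid[-1] > 1e-9 * max(1.0, total):
        grid = np.append(grid, total)
    x = np.interp(grid, s, xy[:, 0])
    y = np.interp(grid, s, xy[:, 1])
    return np.column_stack([x, y])


def _in_corridor(xy: np.ndarray, release: np.ndarray, goal: np.ndarray, width: float) -> np.ndarray:
    """Boolean mask: points inside the rotated corridor rectangle joining
    release point and goal centre."""
    axis = goal - release
    length = float(np.hypot(*axis))
    if length <= 1e-12:
        return np.hypot(xy[:, 0] - goal[0], xy[:, 1] - goal[1]) <= width / 2.0
    u = axis / length
    rel = xy - release
    along = rel @ u
    perp = rel @ np.array([-u[1], u[0]])
    return (along >= 0.0) & (along <= length) & (np.abs(perp) <= width / 2.0)


def compute_trial_metrics(
    traj: Trajectory,
    arena: ArenaSpec,
    goal_center: tuple[float, float] | None = None,
    release_point: tuple[float, float] | None = None,
    gallagher_rate: float = GALLAGHER_RATE,
    whishaw_spacing: float = WHISHAW_SPACING,
) -> TrialMetrics:
    """Compute the per-trial behavioural variables.

    ``goal_center`` defaults to the arena's goal for the trial phase
    (the former platform in removal trials, the reflected platform in
    reversal).  ``release_point`` defaults to the first sample.
    """
    if traj.n_samples == 0:
        raise ValueError("empty trajectory")
    goal = np.asarray(
        goal_center if goal_center is not None else arena.goal_for_phase(traj.phase), dtype=float
    )
    if np.hypot(*goal) >= arena.pool_radius:
        raise ValueError("goal centre must lie inside the pool")
    release = np.asarray(
        release_point if release_point is not None else traj.xy[0], dtype=float
    )

    xy = traj.xy
    t = traj.t
    dist_goal = np.hypot(xy[:, 0] - goal[0], xy[:, 1] - goal[1])

    inside = dist_goal <= arena.platform_radius
    if inside.any():
        first = int(np.argmax(inside))
        entry_latency, entry_censored = float(t[first]), False
    else:
        entry_latency, entry_censored = float(arena.max_trial_duration), True
    latency, censored = entry_latency, entry_censored

    seg = np.hypot(*np.diff(xy, axis=0).T) if traj.n_samples > 1 else np.array([])
    path_length = float(seg.sum())
    mean_speed = path_length / latency if latency > 0 else 0.0

    r = np.hypot(xy[:, 0], xy[:, 1])
    thigmotaxis_pct = 100.0 * float(np.mean(r >= arena.periphery_radius))

    gallagher_index = float(dist_goal.mean())

    coarse = resample_path(traj, gallagher_rate) if traj.n_samples > 1 else traj
    gd = np.hypot(coarse.xy[:, 0] - goal[0], coarse.xy[:, 1] - goal[1])
    gallagher_distance = float(gd.sum())

    arc = resample_arclength(xy, whishaw_spacing)
    in_corr = _in_corridor(arc, release, goal, arena.corridor_width)
    whishaw_pct = 100.0 * float(in_corr.mean())

    sgx, sgy = np.sign(goal[0]), np.sign(goal[1])
    in_quad = (xy[:, 0] * sgx >= 0.0) & (xy[:, 1] * sgy >= 0.0)
    target_quadrant_pct = 100.0 * float(np.mean(in_quad))

    return TrialMetrics(
        mouse_id=traj.mouse_id,
        group=traj.group,
        phase=traj.phase,
        session=traj.session,
        trial=traj.trial,
        latency=latency,
        censored=censored,
        first_entry_latency=entry_latency,
        first_entry_censored=entry_censored,
        path_length=path_length,
        mean_speed=mean_speed,
        thigmotaxis_pct=thigmotaxis_pct,
        whishaw_pct=whishaw_pct,
        gallagher_index=gallagher_index,
        gallagher_distance=gallagher_distance,
        target_quadrant_pct=target_quadrant_pct,
    )


def metrics_table(
    trajectories: list[Trajectory],
    arena: ArenaSpec,
    release_points: np.ndarray | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Tidy per-trial metrics table, one row per trial."""
    pts = np.asarray(release_points if release_points is not None else arena.release_points, float)
    rows = []
    for traj in trajectories:
        rel = pts[traj.release_index] if traj.release_index < len(pts) else traj.xy[0]
        rows.append(compute_trial_metrics(traj, arena, release_point=rel, **kwargs).as_dict())
    return pd.DataFrame(rows)


def session_average(trial_df: pd.DataFrame) -> pd.DataFrame:
    """Average the trials of each (mouse, phase, session) into one metric
    vector per session.  Censored latencies enter at the censoring bound;
    the session is flagged censored only when every trial was.
    """
    required = {"mouse_id", "group", "phase", "session", *METRIC_VARIABLES}
    missing = required - set(trial_df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if trial_df.empty:
        return trial_df.copy()
    keys = ["mouse_id", "group", "phase", "session"]
    if trial_df.groupby(["mouse_id", "phase", "session"])["group"].nunique().max() > 1:
        raise ValueError("a mouse appears under two groups")
    agg = {var: "mean" for var in METRIC_VARIABLES}
    extra = {}
    if "censored" in trial_df.columns:
        extra["censored"] = ("censored", "all")
    if "gallagher_distance" in trial_df.columns:
        agg["gallagher_distance"] = "mean"
    if "first_entry_latency" in trial_df.columns:
        agg["first_entry_latency"] = "mean"
    out = (
        trial_df.groupby(keys, sort=True, as_index=False)
        .agg(n_trials=("session", "size"), **{k: (k, v) for k, v in agg.items()}, **extra)
    )
    return out


def discrimination_index(novel_time: float, familiar_time: float) -> RecognitionResult:
    """Discrimination index DI = 100 * (novel - familiar) / total, in %."""
    if novel_time < 0 or familiar_time < 0:
        raise ValueError("exploration times must be >= 0")
    total = novel_time + familiar_time
    if total <= 0:
        raise ValueError("total exploration time is zero; DI undefined")
    di = 100.0 * (novel_time / total - familiar_time / total)
    return RecognitionResult(novel_time=float(novel_time), familiar_time=float(familiar_time), di=di)


def apply_inclusion_filters(
    trial_df: pd.DataFrame,
    cue_threshold: float = 30.0,
    manual_exclusions: dict[str, str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude mice that failed the cued (visible-platform) session.

    A mouse is retained only when its cue latency is strictly below
    ``cue_threshold`` seconds.  User-supplied exclusions (e.g. an
    over-performing animal) are applied afterwards.  Returns the retained
    mouse ids and an exclusion log with one row per excluded mouse.
    """
    log_cols = ["mouse_id", "reason", "detail"]
    if trial_df.empty:
        return [], pd.DataFrame(columns=log_cols)
    mice = list(pd.unique(trial_df["mouse_id"]))
    cue = trial_df[trial_df["phase"] == "CUE"]
    cue_latency = cue.groupby("mouse_id")["latency"].min()
    missing = [m for m in mice if m not in cue_latency.index]
    if missing:
        raise ValueError(f"mice without a cue trial: {missing}")
    log = []
    retained = []
    manual = manual_exclusions or {}
    for m in mice:
        if cue_latency[m] >= cue_threshold:
            log.append(dict(mouse_id=m, reason="cue_criterion",
                            detail=f"cue latency {cue_latency[m]:.1f} s >= {cue_threshold:g} s"))
        elif m in manual:
            log.append(dict(mouse_id=m, reason="manual", detail=manual[m]))
        else:
            retained.append(m)
    unknown = set(manual) - set(mice)
    if unknown:
        raise ValueError(f"manual exclusions name unknown mice: {sorted(unknown)}")
    return retained, pd.DataFrame(log, columns=log_cols)
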