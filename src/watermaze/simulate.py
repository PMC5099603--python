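"""Synthetic cohort generation.

The swim agent is a discrete-time heading process: at each step the new
heading mixes (weight ``w``) a unit vector toward the goal with (weight
``1 - w``) a non-goal heading that blends wall following with persistence
of the current heading; an angular Gaussian perturbation is added, the
position advances by ``speed * dt`` and is reflected at the pool wall.
A trial ends at the first sample inside the platform disc or at the
maximum trial duration.

The generator is fully deterministic given a seed: every trial owns a
child stream spawned from the design seed, so single-trial and whole-
cohort simulation produce bit-identical paths.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import (
    AgentParams,
    ArenaSpec,
    CohortDesign,
    GroupParams,
    Trajectory,
)

__all__ = [
    "simulate_trial",
    "simulate_cohort",
    "simulate_nested_summaries",
    "simulate_metric_table",
]

_EPS = 1e-12
_WALL_GAIN = 3.0  # radial correction gain of the wall-following heading


def _simulate_batch(
    arena: ArenaSpec,
    goal: np.ndarray,
    platform: np.ndarray | None,
    w: np.ndarray,
    bias: np.ndarray,
    speed: np.ndarray,
    noise: np.ndarray,
    release: np.ndarray,
    rngs: Sequence[np.random.Generator],
) -> list[tuple[np.ndarray, np.ndarray, bool]]:
    """Integrate many trials in lock-step.

    ``platform`` is the escape disc centre or None (no escape possible,
    e.g. a removal trial); ``goal`` is the location the agent steers
    toward.  Returns per trial (t, xy, escaped).
    """
    n = release.shape[0]
    steps = arena.n_steps
    dt = arena.dt
    pr = arena.pool_radius

    # Per-trial noise streams drawn up front keeps the stepping loop
    # vectorised while preserving one-stream-per-trial reproducibility.
    eps = np.empty((n, steps))
    for i, rng in enumerate(rngs):
        eps[i] = rng.standard_normal(steps)

    pos = release.astype(float).copy()
    # Initial heading: toward the pool centre.
    heading = -pos.copy()
    norms = np.hypot(heading[:, 0], heading[:, 1])
    zero = norms < _EPS
    heading[zero] = (1.0, 0.0)
    heading[~zero] /= norms[~zero, None]

    path = np.empty((steps + 1, n, 2))
    path[0] = pos
    escape_step = np.full(n, -1, dtype=int)
    active = np.ones(n, dtype=bool)
    r_band = (1.0 - arena.periphery_fraction / 2.0) * pr
    step_len = speed * dt
    ang_sd = noise * math.sqrt(dt)

    for k in range(steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        p = pos[idx]
        h = heading[idx]

        d = goal - p
        dist = np.hypot(d[:, 0], d[:, 1])
        u_goal = np.where(dist[:, None] > _EPS, d / np.maximum(dist, _EPS)[:, None], h)

        r = np.hypot(p[:, 0], p[:, 1])
        rhat = np.where(r[:, None] > _EPS, p / np.maximum(r, _EPS)[:, None], h)
        that = np.stack([-rhat[:, 1], rhat[:, 0]], axis=1)
        u_wall = that + (_WALL_GAIN * (r_band - r) / pr)[:, None] * rhat
        wn = np.hypot(u_wall[:, 0], u_wall[:, 1])
        u_wall = np.where(wn[:, None] > _EPS, u_wall / np.maximum(wn, _EPS)[:, None], h)

        u_non = bias[idx, None] * u_wall + (1.0 - bias[idx, None]) * h
        nn = np.hypot(u_non[:, 0], u_non[:, 1])
        u_non = np.where(nn[:, None] > _EPS, u_non / np.maximum(nn, _EPS)[:, None], h)

        v = w[idx, None] * u_goal + (1.0 - w[idx, None]) * u_non
        vn = np.hypot(v[:, 0], v[:, 1])
        v = np.where(vn[:, None] > _EPS, v, h)

        ang = np.arctan2(v[:, 1], v[:, 0]) + ang_sd[idx] * eps[idx, k]
        dirv = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        newp = p + step_len[idx, None] * dirv

        rn = np.hypot(newp[:, 0], newp[:, 1])
        out = rn > pr
        if np.any(out):
            # Fold the overshoot back inside and reflect the heading about
            # the tangent at the crossing point.
            scale = (2.0 * pr - rn[out]) / rn[out]
            nhat = newp[out] / rn[out, None]
            newp[out] *= scale[:, None]
            dot = np.einsum("ij,ij->i", dirv[out], nhat)
            dirv[out] -= 2.0 * dot[:, None] * nhat

        pos[idx] = newp
        heading[idx] = dirv
        path[k + 1, idx] = newp

        if platform is not None:
            on = np.hypot(newp[:, 0] - platform[0], newp[:, 1] - platform[1]) <= arena.platform_radius
            if np.any(on):
                hit = idx[on]
                escape_step[hit] = k + 1
                active[hit] = False

    out_list = []
    for i in range(n):
        last = escape_step[i] if escape_step[i] >= 0 else steps
        t = np.arange(last + 1) * dt
        out_list.append((t, path[: last + 1, i].copy(), escape_step[i] >= 0))
    return out_list


def simulate_trial(
    arena: ArenaSpec,
    params: AgentParams,
    platform_center: tuple[float, float] | None,
    release_point: tuple[float, float],
    seed: int | np.random.Generator = 0,
    goal_center: tuple[float, float] | None = None,
    mouse_id: str = "m0",
    group: str = "NA",
    phase: str = "ACQ",
    session: int = 1,
    trial: int = 1,
    release_index: int = 0,
) -> Trajectory:
    """Simulate one trial.

    ``platform_center=None`` disables escape (removal trial); the agent
    then steers toward ``goal_center`` (the remembered platform).
    """
    if goal_center is None:
        if platform_center is None:
            raise ValueError("goal_center required when there is no platform")
        goal_center = platform_center
    rx, ry = release_point
    if abs(math.hypot(rx, ry) - arena.pool_radius) > 1e-6 * max(1.0, arena.pool_radius):
        raise ValueError("release point must lie on the pool wall")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    res = _simulate_batch(
        arena,
        goal=np.asarray(goal_center, dtype=float),
        platform=None if platform_center is None else np.asarray(platform_center, dtype=float),
        w=np.array([params.goal_weight]),
        bias=np.array([params.thigmotaxis_bias]),
        speed=np.array([params.speed]),
        noise=np.array([params.heading_noise]),
        release=np.array([release_point], dtype=float),
        rngs=[rng],
    )
    t, xy, escaped = res[0]
    traj = Trajectory(mouse_id, group, phase, session, trial, t, xy, escaped, release_index)
    traj.validate(arena, goal=platform_center)
    return traj


def _trial_plan(design: CohortDesign, arena: ArenaSpec) -> pd.DataFrame:
    """Enumerate every (mouse, phase, session, trial) with its goal weight,
    steering target and release schedule.  Row order defines the seed
    stream order and is therefore part of the reproducibility contract.
    """
    acq = design.phase_spec("ACQ")
    rows = []
    schedule_ss, ability_ss, trial_ss = np.random.SeedSequence(design.seed).spawn(3)
    sched_rng = np.random.default_rng(schedule_ss)
    ability_rng = np.random.default_rng(ability_ss)
    n_release = len(arena.release_points)
    for g in design.groups:
        for m in range(g.size):
            mouse_id = f"{g.name}_{m + 1:02d}"
            ability = ability_rng.normal(0.0, g.ability_sd) if g.ability_sd > 0 else 0.0
            for ps in design.phases:
                for s in range(1, ps.n_sessions + 1):
                    # Balanced release schedule: without replacement within
                    # each session, cycling if the session is longer.
                    order = []
                    while len(order) < ps.n_trials:
                        order.extend(sched_rng.permutation(n_release).tolist())
                    for tr in range(1, ps.n_trials + 1):
                        if ps.phase == "ACQ":
                            w = g.goal_weight(s)
                        elif ps.phase == "REM":
                            w = g.goal_weight(acq.n_sessions)
                        elif ps.phase == "CUE":
                            w = design.cue_goal_weight
                        else:  # REV: re-learning toward the reflected goal
                            w = g.goal_weight(s)
                        rows.append(
                            dict(
                                mouse_id=mouse_id,
                                group=g.name,
                                phase=ps.phase,
                                session=s,
                                trial=tr,
                                goal_weight=w,
                                ability=0.0 if ps.phase == "CUE" else ability,
                                trial_w_sd=0.0 if ps.phase == "CUE" else g.trial_w_sd,
                                thigmotaxis_bias=0.0 if ps.phase == "CUE" else g.thigmotaxis_bias,
                                heading_noise=design.cue_heading_noise if ps.phase == "CUE" else g.heading_noise,
                                mean_speed=g.mean_speed,
                                speed_sd=g.speed_sd,
                                release_index=order[tr - 1],
                            )
                        )
    plan = pd.DataFrame(rows)
    plan["trial_seed_seq"] = trial_ss.spawn(len(plan))
    return plan


def simulate_cohort(
    design: CohortDesign, arena: ArenaSpec | None = None
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate every trial of a cohort.

    Returns the trajectories plus per-trial metadata (goal weight, speed
    draw, release index).  Bit-identical under a fixed design seed.
    """
    arena = arena or ArenaSpec()
    plan = _trial_plan(design, arena)
    mouse_ids = plan["mouse_id"].unique()
    if len(mouse_ids) != sum(g.size for g in design.groups):
        raise ValueError("duplicate mouse ids in cohort design")

    rngs = [np.random.default_rng(ss) for ss in plan["trial_seed_seq"]]
    # First draws of each trial stream: the swim speed, then the
    # goal-weight jitter for that trial.
    speeds = np.array(
        [
            max(0.0, rng.normal(mu, sd) if sd > 0 else mu)
            for rng, mu, sd in zip(rngs, plan["mean_speed"], plan["speed_sd"])
        ]
    )
    w_eff = np.array(
        [
            float(np.clip(w + ab + (rng.normal(0.0, sd) if sd > 0 else 0.0), 0.0, 1.0))
            for rng, w, ab, sd in zip(
                rngs, plan["goal_weight"], plan["ability"], plan["trial_w_sd"]
            )
        ]
    )
    plan = plan.assign(speed=speeds, effective_goal_weight=w_eff)

    rev_center = np.asarray(arena.reversal_center())
    acq_center = np.asarray(arena.platform_center)
    release_pts = np.asarray(arena.release_points, dtype=float)

    trajectories: list[Trajectory] = [None] * len(plan)  # type: ignore[list-item]
    for phase, sub in plan.groupby("phase", sort=False):
        goal = rev_center if phase == "REV" else acq_center
        platform = None if phase == "REM" else goal
        idx = sub.index.to_numpy()
        res = _simulate_batch(
            arena,
            goal=goal,
            platform=platform,
            w=sub["effective_goal_weight"].to_numpy(),
            bias=sub["thigmotaxis_bias"].to_numpy(),
            speed=sub["speed"].to_numpy(),
            noise=sub["heading_noise"].to_numpy(),
            release=release_pts[sub["release_index"].to_numpy()],
            rngs=[rngs[i] for i in idx],
        )
        for i, (t, xy, escaped) in zip(idx, res):
            row = plan.loc[i]
            trajectories[i] = Trajectory(
                mouse_id=row["mouse_id"],
                group=row["group"],
                phase=phase,
                session=int(row["session"]),
                trial=int(row["trial"]),
                t=t,
                xy=xy,
                escaped=escaped,
                release_index=int(row["release_index"]),
            )
    meta = plan.drop(columns=["trial_seed_seq"])
    return trajectories, meta


def simulate_nested_summaries(
    group_means: dict[str, float] | Sequence[float],
    mice_per_group: int,
    units_per_mouse: int,
    between_mouse_sd: float,
    residual_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Nested summary table: value = group mean + mouse effect + residual.

    Emulates per-image puncta or per-dendrite spine summaries, with mouse
    as the clustering unit.  Returns columns group, mouse_id, unit, value.
    """
    if mice_per_group < 1 or units_per_mouse < 1:
        raise ValueError("counts must be >= 1")
    if between_mouse_sd < 0 or residual_sd < 0:
        raise ValueError("sds must be >= 0")
    if not isinstance(group_means, dict):
        group_means = {f"G{i + 1}": m for i, m in enumerate(group_means)}
    rng = np.random.default_rng(seed)
    rows = []
    for gname, gmean in group_means.items():
        if not math.isfinite(float(gmean)):
            raise ValueError(f"group mean for {gname!r} must be finite")
        for m in range(mice_per_group):
            mouse_effect = rng.normal(0.0, between_mouse_sd) if between_mouse_sd > 0 else 0.0
            mouse_id = f"{gname}_m{m + 1:02d}"
            for u in range(units_per_mouse):
                resid = rng.normal(0.0, residual_sd) if residual_sd > 0 else 0.0
                rows.append(
                    dict(group=gname, mouse_id=mouse_id, unit=u + 1, value=gmean + mouse_effect + resid)
                )
    return pd.DataFrame(rows)


# Mapping from the latent learning level L in [0, 1] to the seven
# session-level behavioural variables: (intercept, slope, noise scale).
_METRIC_MODEL = {
    "latency": (55.0, -45.0, 6.0),
    "target_quadrant_pct": (22.0, 38.0, 6.0),
    "thigmotaxis_pct": (50.0, -38.0, 6.0),
    "whishaw_pct": (8.0, 70.0, 7.0),
    "gallagher_index": (48.0, -28.0, 4.0),
    "path_length": (1150.0, -850.0, 110.0),
    "mean_speed": (20.0, 0.0, 2.0),
}
_METRIC_BOUNDS = {
    "latency": (1.0, 60.0),
    "target_quadrant_pct": (0.0, 100.0),
    "thigmotaxis_pct": (0.0, 100.0),
    "whishaw_pct": (0.0, 100.0),
    "gallagher_index": (1.0, 2.0 * 85.0),
    "path_length": (10.0, np.inf),
    "mean_speed": (1.0, np.inf),
}


def simulate_metric_table(
    group_sizes: dict[str, int],
    n_sessions: int = 5,
    seed: int = 0,
    w0: float = 0.2,
    rate: float = 0.15,
    group_shift: dict[str, float] | None = None,
    mouse_sd: float = 0.08,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Gaussian surrogate for session-averaged metric vectors.

    Each mouse carries a latent learning level L(s) = clip(w0 + shift_g +
    a_i + rate * (s - 1), 0, 1) with mouse ability a_i ~ N(0, mouse_sd^2);
    the seven variables are affine in L plus independent Gaussian noise.
    Orders of magnitude mirror the trajectory-derived metrics, at a tiny
    fraction of the cost — used for statistical calibration experiments.
    """
    rng = np.random.default_rng(seed)
    shift = group_shift or {}
    rows = []
    for gname, size in group_sizes.items():
        for m in range(size):
            a = rng.normal(0.0, mouse_sd) if mouse_sd > 0 else 0.0
            mouse_id = f"{gname}_{m + 1:02d}"
            for s in range(1, n_sessions + 1):
                lvl = float(np.clip(w0 + shift.get(gname, 0.0) + a + rate * (s - 1), 0.0, 1.0))
                rec = dict(mouse_id=mouse_id, group=gname, phase="ACQ", session=s)
                for var, (b0, b1, nsd) in _METRIC_MODEL.items():
                    lo, hi = _METRIC_BOUNDS[var]
                    val = b0 + b1 * lvl + rng.normal(0.0, nsd * noise_scale)
                    rec[var] = float(np.clip(val, lo, hi))
                rows.append(rec)
    return pd.DataFrame(rows)
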