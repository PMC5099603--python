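"""Arena geometry, cohort design, and trajectory containers.

Coordinates are pool-centered centimetres.  The acquisition platform sits in
the (+, +) quadrant so that the quadrant containing the goal is unambiguous
(quadrants are split by the coordinate axes through the pool centre) and the
180-degree reversal is a simple sign flip of the platform centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PHASES",
    "ArenaSpec",
    "AgentParams",
    "GroupParams",
    "PhaseSpec",
    "CohortDesign",
    "Trajectory",
    "ts65dn_replica",
]

#: Recognised trial phases: acquisition, removal (probe), cued, reversal.
PHASES = ("ACQ", "REM", "CUE", "REV")

_WALL_TOL = 1e-6


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and timing of the water maze.

    Defaults follow a 1.70 m pool with a 12 cm hidden platform, 60 s trials
    and a 25 Hz tracker.  ``periphery_fraction`` is the width of the outer
    (thigmotaxis) annulus as a fraction of the pool radius;
    ``corridor_width`` is the width of the optimal release-to-goal corridor
    used by the Whishaw index.
    """

    pool_radius: float = 85.0
    platform_center: tuple[float, float] = (21.25, 29.75)
    platform_radius: float = 6.0
    periphery_fraction: float = 0.2
    corridor_width: float = 12.0
    max_trial_duration: float = 60.0
    sample_rate: float = 25.0
    release_points: tuple[tuple[float, float], ...] = (
        (85.0, 0.0),
        (0.0, 85.0),
        (-85.0, 0.0),
        (0.0, -85.0),
    )

    def __post_init__(self) -> None:
        for name in ("pool_radius", "platform_radius", "max_trial_duration", "sample_rate"):
            if _check_finite(name, getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.periphery_fraction < 1.0:
            raise ValueError("periphery_fraction must lie in (0, 1)")
        if self.corridor_width <= 0:
            raise ValueError("corridor_width must be > 0")
        cx, cy = self.platform_center
        if math.hypot(cx, cy) + self.platform_radius >= self.pool_radius:
            raise ValueError("platform must lie entirely inside the pool")
        for i, (px, py) in enumerate(self.release_points):
            if abs(math.hypot(px, py) - self.pool_radius) > _WALL_TOL * max(1.0, self.pool_radius):
                raise ValueError(f"release point {i} is not on the pool wall")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_steps(self) -> int:
        """Number of integration steps in a full-length trial."""
        return int(round(self.max_trial_duration * self.sample_rate))

    @property
    def periphery_radius(self) -> float:
        """Inner radius of the thigmotaxis annulus."""
        return (1.0 - self.periphery_fraction) * self.pool_radius

    def reversal_center(self) -> tuple[float, float]:
        """Platform centre after the 180-degree reversal."""
        return (-self.platform_center[0], -self.platform_center[1])

    def goal_for_phase(self, phase: str) -> tuple[float, float]:
        """Goal location used to score a trial of the given phase.

        ACQ and CUE use the training platform; REM scores proximity to the
        *former* platform position; REV uses the reflected platform.
        """
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        return self.reversal_center() if phase == "REV" else self.platform_center


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the mixture-heading swim agent for a single trial.

    ``goal_weight`` mixes a unit vector toward the platform with a
    non-goal heading that itself blends wall following (weight
    ``thigmotaxis_bias``) with persistence of the current heading.
    ``heading_noise`` is the standard deviation of the per-step angular
    perturbation in rad/sqrt(s).
    """

    goal_weight: float
    thigmotaxis_bias: float
    speed: float
    heading_noise: float

    def __post_init__(self) -> None:
        for name in ("goal_weight", "thigmotaxis_bias", "speed", "heading_noise"):
            _check_finite(name, getattr(self, name))
        if not 0.0 <= self.goal_weight <= 1.0:
            raise ValueError("goal_weight must lie in [0, 1]")
        if not 0.0 <= self.thigmotaxis_bias <= 1.0:
            raise ValueError("thigmotaxis_bias must lie in [0, 1]")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.heading_noise < 0:
            raise ValueError("heading_noise must be >= 0")


@dataclass(frozen=True)
class GroupParams:
    """Per-group simulation parameters of the synthetic cohort.

    The per-session goal weight is min(1, w0 + learning_rate * (session-1)),
    restarting from ``w0`` in the reversal phase.  ``ability_sd`` adds a
    stable per-mouse offset to the goal weight (individual differences);
    ``trial_w_sd`` adds independent per-trial jitter.  The effective trial
    weight is clipped to [0, 1].
    """

    name: str
    size: int
    w0: float
    learning_rate: float
    thigmotaxis_bias: float
    mean_speed: float
    speed_sd: float = 0.0
    heading_noise: float = 1.0
    ability_sd: float = 0.0
    trial_w_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"group {self.name!r}: size must be >= 1")
        if not 0.0 <= self.w0 <= 1.0:
            raise ValueError(f"group {self.name!r}: w0 must lie in [0, 1]")
        if self.learning_rate < 0:
            raise ValueError(f"group {self.name!r}: learning_rate must be >= 0")
        if not 0.0 <= self.thigmotaxis_bias <= 1.0:
            raise ValueError(f"group {self.name!r}: thigmotaxis_bias must lie in [0, 1]")
        if not self.mean_speed > 0:
            raise ValueError(f"group {self.name!r}: mean_speed must be > 0")
        if min(self.speed_sd, self.heading_noise, self.ability_sd, self.trial_w_sd) < 0:
            raise ValueError(f"group {self.name!r}: sds must be >= 0")

    def goal_weight(self, session: int) -> float:
        """Goal weight for 1-based session index within a learning phase."""
        return min(1.0, self.w0 + self.learning_rate * (session - 1))


@dataclass(frozen=True)
class PhaseSpec:
    phase: str
    n_sessions: int
    n_trials: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.n_sessions < 1 or self.n_trials < 1:
            raise ValueError("n_sessions and n_trials must be >= 1")


@dataclass(frozen=True)
class CohortDesign:
    """Groups, phase schedule, and master seed of a synthetic cohort."""

    groups: tuple[GroupParams, ...]
    phases: tuple[PhaseSpec, ...]
    seed: int
    cue_goal_weight: float = 0.95
    cue_heading_noise: float = 0.5

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if not self.groups:
            raise ValueError("at least one group required")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    @property
    def group_names(self) -> list[str]:
        return [g.name for g in self.groups]

    def phase_spec(self, phase: str) -> PhaseSpec:
        for ps in self.phases:
            if ps.phase == phase:
                return ps
        raise KeyError(phase)


def ts65dn_replica(seed: int = 0, size_scale: float = 1.0) -> CohortDesign:
    """Study-replica cohort design: 4 groups, 5 acquisition sessions x 4
    trials, 1 removal trial, 1 cued trial, 3 reversal sessions x 4 trials.

    Group sizes (11, 8, 12, 8) match the analysed cohort.  The simulation
    parameters encode the qualitative group structure: trisomic (TS) mice
    learn slowly, swim slightly slower and hug the wall more; the
    treated trisomic group is partially rescued; the two euploid (WT)
    groups learn normally.
    """
    def n(base: int) -> int:
        return max(1, int(round(base * size_scale)))

    groups = (
        GroupParams("WT", n(11), w0=0.18, learning_rate=0.050,
                    thigmotaxis_bias=0.25, mean_speed=22.0, speed_sd=3.0,
                    heading_noise=1.2, ability_sd=0.06, trial_w_sd=0.09),
        GroupParams("TS", n(8), w0=0.12, learning_rate=0.020,
                    thigmotaxis_bias=0.42, mean_speed=19.0, speed_sd=3.0,
                    heading_noise=1.5, ability_sd=0.06, trial_w_sd=0.09),
        GroupParams("WT-EE-EGCG", n(12), w0=0.19, learning_rate=0.055,
                    thigmotaxis_bias=0.22, mean_speed=23.0, speed_sd=3.0,
                    heading_noise=1.2, ability_sd=0.06, trial_w_sd=0.09),
        GroupParams("TS-EE-EGCG", n(8), w0=0.14, learning_rate=0.040,
                    thigmotaxis_bias=0.33, mean_speed=20.0, speed_sd=3.0,
                    heading_noise=1.4, ability_sd=0.06, trial_w_sd=0.09),
    )
    phases = (
        PhaseSpec("ACQ", 5, 4),
        PhaseSpec("REM", 1, 1),
        PhaseSpec("CUE", 1, 1),
        PhaseSpec("REV", 3, 4),
    )
    return CohortDesign(groups=groups, phases=phases, seed=seed)


@dataclass
class Trajectory:
    """One trial's time-stamped swim path.

    ``t`` starts at 0 with uniform spacing 1/sample_rate; ``xy`` is an
    (n, 2) array of pool-centred positions in cm.  ``escaped`` is True when
    the path ends at the first platform entry.
    """

    mouse_id: str
    group: str
    phase: str
    session: int
    trial: int
    t: np.ndarray
    xy: np.ndarray
    escaped: bool
    release_index: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.xy.shape != (self.t.size, 2):
            raise ValueError("t must be 1-D and xy shaped (len(t), 2)")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def validate(self, arena: ArenaSpec, goal: tuple[float, float] | None = None) -> None:
        """Assert the geometric and timing invariants against an arena."""
        if self.n_samples == 0:
            raise ValueError("empty trajectory")
        if self.t[0] != 0.0 or (self.n_samples > 1 and np.any(np.diff(self.t) <= 0)):
            raise ValueError("t must increase strictly from 0")
        r2 = np.einsum("ij,ij->i", self.xy, self.xy)
        tol = 1e-6 * max(1.0, arena.pool_radius)
        if np.any(np.sqrt(r2) > arena.pool_radius + tol):
            bad = int(np.argmax(np.sqrt(r2) > arena.pool_radius + tol))
            raise ValueError(f"sample {bad} lies outside the pool")
        if self.escaped:
            gx, gy = goal if goal is not None else arena.goal_for_phase(self.phase)
            end = self.xy[-1]
            if math.hypot(end[0] - gx, end[1] - gy) > arena.platform_radius + tol:
                raise ValueError("escaped trajectory does not end on the platform")
            if self.duration > arena.max_trial_duration + arena.dt / 2:
                raise ValueError("escaped trajectory exceeds max_trial_duration")
        else:
            if abs(self.duration - arena.max_trial_duration) > arena.dt / 2:
                raise ValueError("non-escaped trajectory must last max_trial_duration")

    def rotated(self, angle_rad: float) -> "Trajectory":
        """Copy of the trajectory rotated about the pool centre."""
        c, s = math.cos(angle_rad), math.sin(angle_rad)
        rot = np.array([[c, -s], [s, c]])
        return replace(self, t=self.t.copy(), xy=self.xy @ rot.T)
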