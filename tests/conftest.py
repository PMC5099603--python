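import numpy as np
import pandas as pd
import pytest

from watermaze.arena import ArenaSpec, Trajectory
from watermaze.simulate import simulate_metric_table


@pytest.fixture(scope="session")
def arena() -> ArenaSpec:
    return ArenaSpec()


def make_path(t, xy, *, phase="ACQ", escaped=False, mouse="m1", group="G",
              session=1, trial=1) -> Trajectory:
    return Trajectory(mouse_id=mouse, group=group, phase=phase, session=session,
                      trial=trial, t=np.asarray(t, float),
                      xy=np.asarray(xy, float), escaped=escaped)


def random_path(rng: np.random.Generator, arena: ArenaSpec, n: int = 200,
                duration: float = 60.0) -> Trajectory:
    """A smooth random path inside the pool (not a physical swim)."""
    t = np.linspace(0.0, duration, n)
    steps = rng.normal(scale=4.0, size=(n, 2)).cumsum(axis=0)
    steps -= steps.mean(axis=0)
    r = np.hypot(steps[:, 0], steps[:, 1]).max()
    xy = steps * (0.95 * arena.pool_radius / max(r, 1e-9))
    return make_path(t, xy)


@pytest.fixture(scope="session")
def replica_metric_table() -> pd.DataFrame:
    """Gaussian surrogate cohort with the study's group structure:
    39 mice in 4 groups, 5 sessions, impaired TS and partially rescued
    treated TS."""
    return simulate_metric_table(
        {"WT": 11, "TS": 8, "WT-EE-EGCG": 12, "TS-EE-EGCG": 8},
        n_sessions=5, seed=42,
        group_shift={"TS": -0.35, "TS-EE-EGCG": -0.15, "WT-EE-EGCG": 0.02},
    )
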