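"""Trial metrics: closed-form cases, geometric oracles, invariances."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from watermaze.arena import ArenaSpec
from watermaze.metrics import (
    METRIC_VARIABLES,
    apply_inclusion_filters,
    compute_trial_metrics,
    discrimination_index,
    resample_arclength,
    resample_path,
    session_average,
)

from conftest import make_path, random_path


def brute_force_in_rect(p, release, goal, width):
    """Independent point-in-rotated-rectangle check (scalar, explicit)."""
    ax, ay = goal[0] - release[0], goal[1] - release[1]
    length = math.hypot(ax, ay)
    ux, uy = ax / length, ay / length
    rx, ry = p[0] - release[0], p[1] - release[1]
    along = rx * ux + ry * uy
    perp = -rx * uy + ry * ux
    return 0.0 <= along <= length and abs(perp) <= width / 2.0


class TestResample:
    def test_25hz_to_1hz_sample_count(self, arena):
        t = np.arange(0, 60.0 + 1e-9, 0.04)
        traj = make_path(t, np.zeros((t.size, 2)))
        out = resample_path(traj, 1.0)
        assert out.n_samples == 61

    def test_linear_path_invariant(self, arena):
        t = np.linspace(0, 10, 251)
        xy = np.column_stack([2.0 * t, -1.5 * t])
        traj = make_path(t, xy)
        for rate in (1.0, 5.0, 40.0):
            out = resample_path(traj, rate)
            seg = np.hypot(*np.diff(out.xy, axis=0).T).sum()
            assert seg == pytest.approx(np.hypot(20, 15), abs=1e-9)
            assert out.t[0] == 0.0 and out.t[-1] == pytest.approx(10.0)

    def test_resampling_never_lengthens(self, arena):
        rng = np.random.default_rng(0)
        for _ in range(20):
            traj = random_path(rng, arena)
            orig = np.hypot(*np.diff(traj.xy, axis=0).T).sum()
            res = resample_path(traj, 3.0)
            new = np.hypot(*np.diff(res.xy, axis=0).T).sum()
            assert new <= orig + 1e-9

    def test_single_sample_warns_and_passes_through(self):
        traj = make_path([0.0], [[1.0, 2.0]])
        with pytest.warns(RuntimeWarning):
            out = resample_path(traj, 5.0)
        assert out is traj

    def test_arclength_uniform_spacing(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 5.0]])
        out = resample_arclength(xy, spacing=1.0)
        seg = np.hypot(*np.diff(out, axis=0).T)
        assert np.allclose(seg, 1.0)
        assert np.allclose(out[0], [0, 0]) and np.allclose(out[-1], [10, 5])


class TestTrialMetrics:
    def test_stationary_mouse_closed_form(self, arena):
        """At rest 40 cm from the goal for 60 s: proximity index 40 cm and
        1 Hz accumulated distance 61 * 40 = 2440 cm, censored."""
        goal = np.asarray(arena.platform_center)
        u = goal / np.linalg.norm(goal)
        pos = goal + 40.0 * u
        t = np.arange(0, 60.0 + 1e-9, 0.04)
        traj = make_path(t, np.tile(pos, (t.size, 1)))
        m = compute_trial_metrics(traj, arena)
        assert m.gallagher_index == pytest.approx(40.0, abs=1e-9)
        assert m.gallagher_distance == pytest.approx(2440.0, abs=1e-6)
        assert m.censored and m.latency == 60.0

    def test_straight_optimal_path(self, arena):
        release = np.array([85.0, 0.0])
        goal = np.asarray(arena.platform_center)
        speed = 20.0
        length = np.linalg.norm(goal - release)
        tt = np.linspace(0, length / speed, 400)
        xy = release + np.outer(tt / tt[-1], goal - release)
        traj = make_path(tt, xy, escaped=True)
        m = compute_trial_metrics(traj, arena, release_point=release)
        assert m.whishaw_pct == pytest.approx(100.0)
        # first within-platform sample, not the endpoint, sets the latency
        d = np.hypot(xy[:, 0] - goal[0], xy[:, 1] - goal[1])
        expect = tt[np.argmax(d <= arena.platform_radius)]
        assert m.latency == pytest.approx(expect)

    def test_zigzag_whishaw_matches_rect_oracle(self, arena):
        rng = np.random.default_rng(4)
        release = np.array([0.0, -85.0])
        goal = np.asarray(arena.platform_center)
        for _ in range(10):
            traj = random_path(rng, arena, n=120)
            m = compute_trial_metrics(traj, arena, release_point=release)
            arc = resample_arclength(traj.xy, 1.0)
            count = sum(brute_force_in_rect(p, release, goal, arena.corridor_width)
                        for p in arc)
            assert m.whishaw_pct == pytest.approx(100.0 * count / len(arc), abs=1e-9)

    def test_percentages_match_brute_force_counts(self, arena):
        rng = np.random.default_rng(11)
        goal = np.asarray(arena.platform_center)
        for _ in range(10):
            traj = random_path(rng, arena)
            m = compute_trial_metrics(traj, arena)
            r = [math.hypot(x, y) for x, y in traj.xy]
            thig = 100.0 * sum(v >= arena.periphery_radius for v in r) / len(r)
            quad = 100.0 * sum(x >= 0 and y >= 0 for x, y in traj.xy) / len(traj.xy)
            gall = sum(math.hypot(x - goal[0], y - goal[1]) for x, y in traj.xy) / len(traj.xy)
            assert m.thigmotaxis_pct == pytest.approx(thig, abs=1e-9)
            assert m.target_quadrant_pct == pytest.approx(quad, abs=1e-9)
            assert m.gallagher_index == pytest.approx(gall, abs=1e-9)

    def test_rotation_invariance(self, arena):
        """Rotating path, goal and release together leaves every
        rotation-invariant metric unchanged (the target quadrant is tied
        to the fixed axes and is exempt)."""
        rng = np.random.default_rng(5)
        traj = random_path(rng, arena)
        goal = np.asarray(arena.platform_center)
        release = np.array([85.0, 0.0])
        ang = 0.83
        c, s = math.cos(ang), math.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        m0 = compute_trial_metrics(traj, arena, goal_center=goal, release_point=release)
        m1 = compute_trial_metrics(traj.rotated(ang), arena,
                                   goal_center=rot @ goal, release_point=rot @ release)
        for name in ("latency", "path_length", "mean_speed", "thigmotaxis_pct",
                     "whishaw_pct", "gallagher_index", "gallagher_distance"):
            assert getattr(m1, name) == pytest.approx(getattr(m0, name), abs=1e-9)

    def test_error_cases(self, arena):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError, match="goal"):
            compute_trial_metrics(make_path(t, np.zeros((2, 2))), arena,
                                  goal_center=(90.0, 0.0))


class TestSessionAverage:
    def make_trials(self, latencies, censored):
        rows = []
        for i, (lat, c) in enumerate(zip(latencies, censored)):
            rec = dict(mouse_id="m1", group="G", phase="ACQ", session=1,
                       trial=i + 1, censored=c)
            for var in METRIC_VARIABLES:
                rec[var] = 1.0
            rec["latency"] = lat
            rows.append(rec)
        return pd.DataFrame(rows)

    def test_mean_with_censored_at_bound(self):
        df = self.make_trials([10.0, 20.0, 30.0, 60.0], [False] * 3 + [True])
        out = session_average(df)
        assert out["latency"].iloc[0] == pytest.approx(30.0)
        assert not out["censored"].iloc[0]

    def test_all_censored_flags_session(self):
        df = self.make_trials([60.0] * 4, [True] * 4)
        assert session_average(df)["censored"].iloc[0]

    def test_idempotent_on_identical_trials(self):
        df = self.make_trials([12.0] * 4, [False] * 4)
        out = session_average(df)
        for var in METRIC_VARIABLES:
            expect = 12.0 if var == "latency" else 1.0
            assert out[var].iloc[0] == pytest.approx(expect)

    def test_random_trials_equal_column_means(self):
        rng = np.random.default_rng(8)
        rows = []
        for tr in range(6):
            rec = dict(mouse_id="m1", group="G", phase="ACQ", session=2, trial=tr)
            for var in METRIC_VARIABLES:
                rec[var] = rng.uniform(0, 50)
            rows.append(rec)
        df = pd.DataFrame(rows)
        out = session_average(df)
        for var in METRIC_VARIABLES:
            assert out[var].iloc[0] == pytest.approx(df[var].mean())

    def test_conflicting_group_label_rejected(self):
        df = self.make_trials([10.0] * 2, [False] * 2)
        df.loc[1, "group"] = "H"
        with pytest.raises(ValueError, match="two groups"):
            session_average(df)


class TestDiscriminationIndex:
    @pytest.mark.parametrize("novel,familiar,expect",
                             [(30.0, 30.0, 0.0), (20.0, 0.0, 100.0),
                              (15.0, 5.0, 50.0)])
    def test_known_values(self, novel, familiar, expect):
        assert discrimination_index(novel, familiar).di == pytest.approx(expect)

    @given(a=st.floats(0.0, 1e3), b=st.floats(0.0, 1e3))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_antisymmetry(self, a, b):
        if a + b <= 0:
            return
        assert discrimination_index(a, b).di == pytest.approx(
            -discrimination_index(b, a).di, abs=1e-9)
        assert -100.0 <= discrimination_index(a, b).di <= 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            discrimination_index(0.0, 0.0)
        with pytest.raises(ValueError):
            discrimination_index(-1.0, 2.0)


class TestInclusionFilters:
    def cue_table(self, latencies):
        rows = []
        for i, lat in enumerate(latencies):
            rows.append(dict(mouse_id=f"m{i}", group="G", phase="CUE",
                             session=1, trial=1, latency=lat))
        return pd.DataFrame(rows)

    def test_cue_threshold_boundary(self):
        retained, log = apply_inclusion_filters(self.cue_table([29.9, 30.0, 35.0]))
        assert retained == ["m0"]
        assert set(log["mouse_id"]) == {"m1", "m2"}
        assert (log["reason"] == "cue_criterion").all()

    def test_manual_exclusion_logged(self):
        retained, log = apply_inclusion_filters(
            self.cue_table([5.0, 6.0]), manual_exclusions={"m1": "over-performer"})
        assert retained == ["m0"]
        assert log.iloc[0]["reason"] == "manual"

    def test_empty_cohort(self):
        retained, log = apply_inclusion_filters(pd.DataFrame(
            columns=["mouse_id", "group", "phase", "session", "trial", "latency"]))
        assert retained == [] and log.empty

    def test_missing_cue_trial_names_mouse(self):
        df = self.cue_table([5.0])
        extra = df.copy()
        extra["mouse_id"] = "ghost"
        extra["phase"] = "ACQ"
        with pytest.raises(ValueError, match="ghost"):
            apply_inclusion_filters(pd.concat([df, extra], ignore_index=True))
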