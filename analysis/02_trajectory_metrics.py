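#!/usr/bin/env python
"""Score every trial, apply the cue inclusion criterion, average sessions.

Turns the raw paths from 01 into the seven behavioural variables per
trial (latency, % target quadrant, thigmotaxis, Whishaw index, Gallagher
index, path length, speed), drops mice that failed the visible-platform
criterion (cue latency >= 30 s), and averages the four trials of each
session into one metric vector per mouse and session.
"""

import argparse
from pathlib import Path

from watermaze.arena import ArenaSpec
from watermaze.io import read_trajectories, write_table
from watermaze.metrics import apply_inclusion_filters, metrics_table, session_average


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("scratch/analysis/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("scratch/analysis/metrics"))
    args = ap.parse_args()

    arena = ArenaSpec()
    trajs = read_trajectories(args.cohort / "trajectories.csv", arena)
    trial_df = metrics_table(trajs, arena)
    retained, exclusions = apply_inclusion_filters(trial_df)
    session_df = session_average(trial_df[trial_df.mouse_id.isin(retained)])

    write_table(trial_df, args.outdir / "trial_metrics.csv")
    write_table(session_df, args.outdir / "session_metrics.csv")
    write_table(exclusions, args.outdir / "exclusions.csv")

    print(f"{len(trial_df)} trials scored; {len(retained)} mice retained, "
          f"{len(exclusions)} excluded")
    acq = session_df[session_df.phase == "ACQ"]
    curve = acq.groupby(["group", "session"])["latency"].mean().unstack().round(1)
    print("mean session latency (s):")
    print(curve.to_string())


if __name__ == "__main__":
    main()
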