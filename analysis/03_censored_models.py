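#!/usr/bin/env python
"""Single-variate inference on the acquisition metrics.

Latency is modelled as a right-censored normal (Tobit) on group +
session factors — the global group effect is a 3-df likelihood-ratio
chi-square — while the distance and thigmotaxis variables go through the
random-intercept repeated-measures model.  Post-hoc contrasts of
interest (TS vs WT, treated TS vs TS, treated WT vs WT) are
Benjamini-Hochberg adjusted.
"""

import argparse
from pathlib import Path

import pandas as pd

from watermaze.censored import (
    fit_random_intercept,
    group_pairwise_contrasts,
    latency_group_test,
    posthoc_contrasts,
)
from watermaze.io import write_json, write_table
from watermaze.pipeline import _pairs_for


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--metrics", type=Path, default=Path("scratch/analysis/metrics"))
    ap.add_argument("--outdir", type=Path, default=Path("scratch/analysis/models"))
    args = ap.parse_args()

    session_df = pd.read_csv(args.metrics / "session_metrics.csv")
    acq = session_df[session_df.phase == "ACQ"]

    fit, test = latency_group_test(acq)
    print(f"latency (Tobit, {fit.n_censored}/{fit.n_obs} censored sessions): "
          f"chi2({test['df']}) = {test['chi2']:.2f}, p = {test['p_value']:.2g}")

    frames = []
    pairs = _pairs_for(fit.group_levels)
    tab = posthoc_contrasts(fit, group_pairwise_contrasts(fit, pairs))
    tab.insert(0, "variable", "latency")
    frames.append(tab)

    for var in ("gallagher_index", "gallagher_distance", "thigmotaxis_pct"):
        mfit = fit_random_intercept(acq[var], acq["group"], acq["mouse_id"])
        print(f"{var}: F({mfit.df_num}, {mfit.df_den}) = {mfit.fvalue:.2f}, "
              f"p = {mfit.p_value:.2g}")
        tab = posthoc_contrasts(mfit, group_pairwise_contrasts(mfit, _pairs_for(mfit.group_levels)))
        tab.insert(0, "variable", var)
        frames.append(tab)

    contrasts = pd.concat(frames, ignore_index=True)
    write_table(contrasts, args.outdir / "contrasts_mwm.csv")
    write_json({"latency_group_test": test}, args.outdir / "latency_tobit.json")
    print("\ncontrasts (BH-adjusted):")
    show = contrasts[["variable", "contrast", "estimate", "ci_lower",
                      "ci_upper", "p_adjusted"]].round(3)
    print(show.to_string(index=False))


if __name__ == "__main__":
    main()
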