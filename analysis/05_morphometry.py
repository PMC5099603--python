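#!/usr/bin/env python
"""Morphometry arm: spine density and synaptic puncta mixed models.

Generates nested per-dendrite spine counts and per-image VGLUT1/VGAT
puncta summaries with a trisomic phenotype (reduced spine density,
raised excitation/inhibition density ratio) partially rescued by
treatment, forms the per-image E/I ratios, and routes every endpoint
through the random-intercept mixed model with Holm-gatekept contrasts.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from watermaze.io import write_table
from watermaze.morpho import analyze_morphometry, vglut_vgat_ratios
from watermaze.simulate import simulate_nested_summaries

GROUPS = ("WT", "TS", "WT-EE-EGCG", "TS-EE-EGCG")


def spine_table(seed: int) -> pd.DataFrame:
    # spines/um on 20-um segments; TS deficit, treated TS partially rescued
    means = dict(zip(GROUPS, (1.55, 1.37, 1.43, 1.47)))
    df = simulate_nested_summaries(means, mice_per_group=6, units_per_mouse=8,
                                   between_mouse_sd=0.05, residual_sd=0.12,
                                   seed=seed)
    df = df.rename(columns={"value": "density", "unit": "dendrite_id"})
    df["segment_length"] = 20.0
    df["spine_count"] = np.round(df["density"] * 20.0).astype(int)
    df["density"] = df["spine_count"] / df["segment_length"]
    df["region"] = "CA1"
    return df


def puncta_table(seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    dens = dict(zip(GROUPS, ((0.45, 0.42), (0.52, 0.41), (0.44, 0.42), (0.46, 0.42))))
    for g in GROUPS:
        for m in range(4):
            mouse = f"{g}_m{m + 1}"
            m_eff = rng.normal(0, 0.02, 2)
            for i in range(8):
                area = 1600.0
                for c, (mu_glut, mu_gat) in ((0, dens[g]),):
                    d_glut = max(0.05, mu_glut + m_eff[0] + rng.normal(0, 0.03))
                    d_gat = max(0.05, mu_gat + m_eff[1] + rng.normal(0, 0.03))
                for channel, d in (("VGLUT1", d_glut), ("VGAT", d_gat)):
                    rows.append(dict(
                        mouse_id=mouse, group=g, region="DG",
                        image_id=f"{mouse}_i{i}", channel=channel,
                        puncta_count=int(round(d * area)), image_area=area,
                        mean_puncta_size=max(0.05, rng.normal(0.35, 0.03)),
                        pct_area=float(np.clip(d * 28 + rng.normal(0, 0.8), 0.5, 40)),
                    ))
    return pd.DataFrame(rows)


def report(res) -> None:
    gate = "rejected" if res.global_p < 0.05 else "not rejected"
    print(f"\n{res.endpoint} ({res.region}): global F({res.fit.df_num}, "
          f"{res.fit.df_den}) = {res.fit.fvalue:.2f}, p = {res.global_p:.3g} "
          f"({gate})")
    if res.contrasts.empty:
        print("  no post-hoc contrasts (gatekeeping)")
    else:
        show = res.contrasts[["contrast", "estimate", "ci_lower", "ci_upper",
                              "p_adjusted"]].round(3)
        print(show.to_string(index=False))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("scratch/analysis/morpho"))
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    spines = spine_table(args.seed)
    write_table(spines, args.outdir / "spine_density.csv")
    report(analyze_morphometry(spines, "spine_density", region="CA1"))

    puncta = puncta_table(args.seed + 1)
    ratios, excluded = vglut_vgat_ratios(puncta)
    write_table(puncta, args.outdir / "puncta_summaries.csv")
    write_table(ratios, args.outdir / "vglut_vgat_ratios.csv")
    print(f"\n{len(ratios)} paired images -> E/I ratios ({len(excluded)} excluded)")
    report(analyze_morphometry(ratios, "density_ratio", region="DG"))
    report(analyze_morphometry(ratios, "area_ratio", region="DG"))


if __name__ == "__main__":
    main()
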