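#!/usr/bin/env python
"""Supervised group-median PCA of acquisition and reversal learning.

Fits the PCA on the 20-row (acquisition) and 12-row (reversal)
group-by-session median matrices, projects every mouse-session record as
a supplementary point, decomposes between/within-group variance, checks
axis stability by leave-one-mouse-out jackknifing, and tests pairwise
group separation on PC1 with a label-permutation test that refits the
whole analysis at each shuffle.
"""

import argparse
from pathlib import Path

import pandas as pd

from watermaze.io import write_json, write_table
from watermaze.pca import (
    between_group_variance,
    build_median_matrix,
    fit_group_pca,
    jackknife_stability,
    permutation_test,
    project_individuals,
    within_group_variance_table,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--metrics", type=Path, default=Path("scratch/analysis/metrics"))
    ap.add_argument("--outdir", type=Path, default=Path("scratch/analysis/pca"))
    ap.add_argument("--n-permutations", type=int, default=9999)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    session_df = pd.read_csv(args.metrics / "session_metrics.csv")
    for phase in ("ACQ", "REV"):
        sub = session_df[session_df.phase == phase]
        mm = build_median_matrix(sub, phase=None)
        model = fit_group_pca(mm)
        proj = project_individuals(model, mm, sub)
        tag = phase.lower()
        print(f"\n{phase}: {mm.n_rows}-row median matrix, "
              f"PC1 {model.pct_explained[0]:.0f}% / PC2 {model.pct_explained[1]:.0f}% "
              f"of between-group variance")
        print("PC1 contributions (%):")
        print(model.contributions["PC1"].round(1).to_string())

        bg = between_group_variance(proj, mm)
        print(f"between-group variance: median/origin {bg['between_medians_origin']:.3f}, "
              f"classical {bg['between_classical']:.3f} "
              f"(relative difference {100 * bg['relative_difference']:.1f}%)")

        jk = jackknife_stability(sub, phase=None)
        print(f"jackknife: max PC1 angle {jk.angle_pc1.max():.2f} deg over {len(jk)} deletions")

        perm = permutation_test(sub, phase=None, n_permutations=args.n_permutations,
                                seed=args.seed)
        print("PC1 permutation test (first/last session):")
        print(perm.round(3).to_string(index=False))

        write_json(dict(eigenvalues=model.eigenvalues,
                        pct_explained=model.pct_explained,
                        loadings={c: model.loadings[c].to_dict()
                                  for c in model.loadings},
                        contributions={c: model.contributions[c].to_dict()
                                       for c in model.contributions}),
                   args.outdir / f"pca_{tag}.json")
        write_table(proj, args.outdir / f"supplementary_{tag}.csv")
        wgv = within_group_variance_table(proj)
        write_table(wgv, args.outdir / f"within_group_variance_{tag}.csv")
        write_table(jk, args.outdir / f"jackknife_{tag}.csv")
        write_table(perm, args.outdir / f"permutation_{tag}.csv")


if __name__ == "__main__":
    main()
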