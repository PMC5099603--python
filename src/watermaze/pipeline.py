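"""End-to-end orchestration: simulate -> metrics -> models -> PCA -> reports.

Every stage reads and writes plain CSV/JSON under the run's output
directory, so any stage can be re-run from its on-disk inputs; a manifest
records the configuration hash, seeds and package versions.  All outputs
are deterministic under a fixed config, byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arena import ArenaSpec, CohortDesign, GroupParams, PhaseSpec, ts65dn_replica
from .censored import (
    fit_random_intercept,
    group_pairwise_contrasts,
    latency_group_test,
    posthoc_contrasts,
)
from .io import (
    read_trajectories,
    read_yaml,
    write_json,
    write_table,
    write_trajectories,
    write_yaml,
)
from .metrics import METRIC_VARIABLES, apply_inclusion_filters, metrics_table, session_average
from .pca import (
    between_group_variance,
    build_median_matrix,
    fit_group_pca,
    jackknife_stability,
    permutation_test,
    project_individuals,
    within_group_variance_table,
)
from .simulate import simulate_cohort

__all__ = ["RunConfig", "run_full_analysis", "load_config"]

logger = logging.getLogger(__name__)

#: Contrasts of interest: trisomic vs euploid and each treatment vs its
#: untreated counterpart.
CONTRAST_PAIRS = (("TS", "WT"), ("TS-EE-EGCG", "TS"), ("WT-EE-EGCG", "WT"))


def _pairs_for(levels) -> list[tuple[str, str]]:
    """The study's contrasts of interest when those groups exist,
    otherwise all pairwise comparisons."""
    pairs = [p for p in CONTRAST_PAIRS if set(p) <= set(levels)]
    if not pairs:
        from itertools import combinations
        pairs = list(combinations(levels, 2))
    return pairs


@dataclass
class RunConfig:
    """Everything a full run needs; see the module docstring."""

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    design: CohortDesign | None = None
    trajectories_path: str | None = None
    outdir: str = "results/run"
    seed: int = 0
    cue_threshold_s: float = 30.0
    manual_exclusions: dict = field(default_factory=dict)
    censor_bound_s: float = 60.0
    adjust: str = "bh"
    n_permutations: int = 10_000
    pca_phases: tuple[str, ...] = ("ACQ", "REV")

    def __post_init__(self) -> None:
        if self.design is None and self.trajectories_path is None:
            self.design = ts65dn_replica(seed=self.seed)
        if self.trajectories_path is not None and not Path(self.trajectories_path).exists():
            raise FileNotFoundError(self.trajectories_path)
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (all keys optional)."""
    raw = read_yaml(path) or {}
    kwargs = {}
    if "arena" in raw:
        a = dict(raw["arena"])
        for key in ("platform_center",):
            if key in a:
                a[key] = tuple(a[key])
        if "release_points" in a:
            a["release_points"] = tuple(tuple(p) for p in a["release_points"])
        kwargs["arena"] = ArenaSpec(**a)
    if "design" in raw:
        d = raw["design"]
        if isinstance(d, str) and d == "ts65dn_replica":
            kwargs["design"] = ts65dn_replica(seed=raw.get("seed", 0))
        elif d is not None:
            groups = tuple(GroupParams(**g) for g in d["groups"])
            phases = tuple(PhaseSpec(**p) for p in d["phases"])
            kwargs["design"] = CohortDesign(groups=groups, phases=phases,
                                            seed=d.get("seed", raw.get("seed", 0)))
    for key in ("trajectories_path", "outdir", "seed", "cue_threshold_s",
                "manual_exclusions", "censor_bound_s", "adjust", "n_permutations"):
        if key in raw:
            kwargs[key] = raw[key]
    if "pca_phases" in raw:
        kwargs["pca_phases"] = tuple(raw["pca_phases"])
    return RunConfig(**kwargs)


def stage_simulate(config: RunConfig, outdir: Path):
    if config.trajectories_path is not None:
        logger.info("loading trajectories from %s", config.trajectories_path)
        trajs = read_trajectories(config.trajectories_path, config.arena)
        return trajs
    logger.info("simulating cohort (seed %d)", config.design.seed)
    trajs, meta = simulate_cohort(config.design, config.arena)
    write_trajectories(trajs, outdir / "trajectories.csv")
    write_table(meta, outdir / "trial_plan.csv")
    write_yaml({"groups": [dataclasses.asdict(g) for g in config.design.groups],
                "phases": [dataclasses.asdict(p) for p in config.design.phases],
                "seed": config.design.seed},
               outdir / "cohort_design.yaml")
    return trajs


def stage_metrics(config: RunConfig, trajs, outdir: Path):
    trial_df = metrics_table(trajs, config.arena)
    retained, exclusions = apply_inclusion_filters(
        trial_df, cue_threshold=config.cue_threshold_s,
        manual_exclusions=config.manual_exclusions or None,
    )
    for _, row in exclusions.iterrows():
        logger.info("excluding mouse %s: %s (%s)", row.mouse_id, row.reason, row.detail)
    kept = trial_df[trial_df["mouse_id"].isin(retained)]
    session_df = session_average(kept)
    write_table(trial_df, outdir / "trial_metrics.csv")
    write_table(session_df, outdir / "session_metrics.csv")
    write_table(exclusions, outdir / "exclusions.csv")
    return kept, session_df, exclusions


def stage_models(config: RunConfig, session_df: pd.DataFrame, outdir: Path) -> dict:
    report = {}
    contrast_frames = []
    acq = session_df[session_df["phase"] == "ACQ"]

    fit, group_test = latency_group_test(acq, bound=config.censor_bound_s)
    logger.info("latency Tobit: group chi2(%d) = %.2f, p = %.3g",
                group_test["df"], group_test["chi2"], group_test["p_value"])
    pairs = _pairs_for(fit.group_levels)
    tab = posthoc_contrasts(fit, group_pairwise_contrasts(fit, pairs), adjust=config.adjust)
    tab.insert(0, "variable", "latency")
    tab.insert(1, "model", "tobit")
    contrast_frames.append(tab)
    report["latency_tobit"] = dict(
        coefficients={k: float(v) for k, v in fit.params.items()},
        sigma=fit.sigma, loglik=fit.loglik, n_censored=fit.n_censored,
        converged=fit.converged, group_chi2=group_test["chi2"],
        group_df=group_test["df"], group_p=group_test["p_value"],
    )

    # Repeated-measures group tests for the non-censored variables:
    # random-intercept model on per-session mouse means.
    for var in ("gallagher_index", "gallagher_distance", "thigmotaxis_pct"):
        if var not in acq.columns:
            continue
        mfit = fit_random_intercept(acq[var], acq["group"], acq["mouse_id"])
        pairs = _pairs_for(mfit.group_levels)
        tab = posthoc_contrasts(mfit, group_pairwise_contrasts(mfit, pairs),
                                adjust=config.adjust)
        tab.insert(0, "variable", var)
        tab.insert(1, "model", "random_intercept")
        contrast_frames.append(tab)
        report[var] = dict(F=mfit.fvalue, df=(mfit.df_num, mfit.df_den),
                           p=mfit.p_value, between_var=mfit.between_var,
                           resid_var=mfit.resid_var, converged=mfit.converged)
        logger.info("%s: F(%d, %d) = %.2f, p = %.3g", var, mfit.df_num,
                    mfit.df_den, mfit.fvalue, mfit.p_value)

    contrasts = pd.concat(contrast_frames, ignore_index=True)
    write_table(contrasts, outdir / "contrasts_mwm.csv")
    write_json(report, outdir / "models_mwm.json")
    return report


def stage_pca(config: RunConfig, session_df: pd.DataFrame, outdir: Path) -> dict:
    report = {}
    wgv_frames = []
    for phase in config.pca_phases:
        sub = session_df[session_df["phase"] == phase]
        if sub.empty:
            logger.warning("no sessions for phase %s; skipping PCA", phase)
            continue
        mm = build_median_matrix(sub, phase=None)
        model = fit_group_pca(mm)
        proj = project_individuals(model, mm, sub)
        bg = between_group_variance(proj, mm)
        wgv = within_group_variance_table(proj)
        wgv.insert(0, "phase", phase)
        wgv_frames.append(wgv)
        jk = jackknife_stability(sub, phase=None)
        perm = permutation_test(sub, phase=None,
                                n_permutations=config.n_permutations,
                                seed=config.seed)
        tag = phase.lower()
        write_json(dict(
            n_rows=mm.n_rows,
            groups=mm.groups,
            sessions=[int(s) for s in mm.sessions],
            center=mm.center, scale=mm.scale,
            eigenvalues=model.eigenvalues,
            pct_explained=model.pct_explained,
            loadings={c: model.loadings[c].to_dict() for c in model.loadings},
            contributions={c: model.contributions[c].to_dict() for c in model.contributions},
        ), outdir / f"pca_{tag}.json")
        write_table(proj, outdir / f"supplementary_{tag}.csv")
        write_table(jk, outdir / f"jackknife_{tag}.csv")
        write_table(perm, outdir / f"permutation_{tag}.csv")
        report[phase] = dict(
            n_rows=mm.n_rows,
            pc1_pct=float(model.pct_explained[0]),
            pc2_pct=float(model.pct_explained[1]),
            between_group=bg,
            jackknife_max_pc1=float(jk["angle_pc1"].max()) if len(jk) else np.nan,
            n_supplementary=len(proj),
        )
        logger.info("%s PCA: %d rows, PC1 %.1f%%, PC2 %.1f%%", phase, mm.n_rows,
                    model.pct_explained[0], model.pct_explained[1])
    if wgv_frames:
        write_table(pd.concat(wgv_frames, ignore_index=True),
                    outdir / "within_group_variance.csv")
    return report


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage in order and write the report bundle + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("watermaze")
    root.addHandler(handler)
    try:
        trajs = stage_simulate(config, outdir)
        trial_df, session_df, exclusions = stage_metrics(config, trajs, outdir)
        models_report = stage_models(config, session_df, outdir)
        pca_report = stage_pca(config, session_df, outdir)
    except Exception as exc:
        write_json(dict(status="incomplete", error=str(exc)), outdir / "manifest.json")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = dict(
        status="complete",
        config=config.to_dict(),
        config_hash=config.config_hash(),
        seed=config.seed,
        versions=dict(watermaze=__version__, numpy=np.__version__, pandas=pd.__version__),
        n_trials=len(trajs),
        n_mice_retained=int(session_df["mouse_id"].nunique()),
        n_excluded=len(exclusions),
        median_matrix_rows={k: v["n_rows"] for k, v in pca_report.items()},
        outputs=sorted({p.name for p in outdir.iterdir() if p.is_file()} | {"manifest.json"}),
    )
    write_json(manifest, outdir / "manifest.json")
    return dict(manifest=manifest, models=models_report, pca=pca_report,
                outdir=outdir)
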