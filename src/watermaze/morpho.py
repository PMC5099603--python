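"""Morphometric endpoints: spine densities, synaptic puncta summaries and
VGLUT1/VGAT excitation/inhibition ratios, routed through the
random-intercept mixed model with gatekept post-hoc contrasts.

Analysis is at the image/dendrite level with mouse as the clustering
unit; the global F test gates the three contrasts of interest, which are
adjusted for family-wise error (Holm) by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .censored import MixedFit, fit_random_intercept, group_pairwise_contrasts, posthoc_contrasts

__all__ = ["vglut_vgat_ratios", "analyze_morphometry", "MorphoResult", "ENDPOINTS"]

logger = logging.getLogger(__name__)

REGIONS = ("DG", "CA1")
CHANNELS = ("VGLUT1", "VGAT")

#: endpoint name -> column expected in the records table
ENDPOINTS = {
    "spine_density": "density",
    "puncta_density": "density",
    "puncta_size": "mean_puncta_size",
    "pct_area": "pct_area",
    "density_ratio": "density_ratio",
    "area_ratio": "area_ratio",
}

#: The contrasts of interest: trisomic vs euploid, and each treated group
#: vs its untreated counterpart.
DEFAULT_PAIRS = (("TS", "WT"), ("TS-EE-EGCG", "TS"), ("WT-EE-EGCG", "WT"))


def vglut_vgat_ratios(puncta_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image VGLUT1/VGAT ratios of puncta density and % area occupied.

    Expects one row per (image, channel) with columns mouse_id, group,
    region, image_id, channel, puncta_count, image_area, pct_area.  Images
    whose VGAT denominator is zero (or that miss a channel) are excluded
    and logged; the exclusion table names both the image and the reason so
    a dropped image never disappears silently.
    """
    need = {"mouse_id", "group", "region", "image_id", "channel",
            "puncta_count", "image_area", "pct_area"}
    missing = need - set(puncta_df.columns)
    if missing:
        raise ValueError(f"puncta table missing columns: {sorted(missing)}")
    bad_chan = set(puncta_df["channel"]) - set(CHANNELS)
    if bad_chan:
        raise ValueError(f"unknown channels: {sorted(bad_chan)}")
    if (puncta_df["puncta_count"] < 0).any():
        raise ValueError("puncta_count must be >= 0")
    if (puncta_df["image_area"] <= 0).any():
        raise ValueError("image_area must be > 0")

    df = puncta_df.assign(density=puncta_df["puncta_count"] / puncta_df["image_area"])
    rows, excluded = [], []
    for (mouse, group, region, image), sub in df.groupby(
        ["mouse_id", "group", "region", "image_id"], sort=False
    ):
        chans = {c: r for c, r in zip(sub["channel"], sub.to_dict("records"))}
        if set(chans) != set(CHANNELS):
            excluded.append(dict(mouse_id=mouse, region=region, image_id=image,
                                 reason="missing_channel"))
            continue
        vglut, vgat = chans["VGLUT1"], chans["VGAT"]
        if vgat["density"] <= 0 or vgat["pct_area"] <= 0:
            excluded.append(dict(mouse_id=mouse, region=region, image_id=image,
                                 reason="zero_vgat_denominator"))
            logger.warning("excluding image %s/%s/%s: zero VGAT denominator",
                           mouse, region, image)
            continue
        rows.append(dict(
            mouse_id=mouse, group=group, region=region, image_id=image,
            density_ratio=vglut["density"] / vgat["density"],
            area_ratio=vglut["pct_area"] / vgat["pct_area"],
        ))
    cols = ["mouse_id", "group", "region", "image_id", "density_ratio", "area_ratio"]
    xcols = ["mouse_id", "region", "image_id", "reason"]
    return (pd.DataFrame(rows, columns=cols), pd.DataFrame(excluded, columns=xcols))


@dataclass
class MorphoResult:
    endpoint: str
    region: str | None
    fit: MixedFit
    global_p: float
    contrasts: pd.DataFrame  # empty when the global test does not reject


def analyze_morphometry(
    records: pd.DataFrame,
    endpoint: str,
    region: str | None = None,
    pairs=DEFAULT_PAIRS,
    adjust: str = "holm",
    alpha: float = 0.05,
) -> MorphoResult:
    """Mixed-model analysis of one morphometric endpoint.

    Fits value ~ group with a per-mouse random intercept and reports the
    contrasts of interest only when the global F test rejects at
    ``alpha`` (gatekeeping).  Pairs absent from the data fall back to all
    pairwise comparisons.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; choose from {sorted(ENDPOINTS)}")
    col = ENDPOINTS[endpoint]
    df = records
    if region is not None:
        if "region" not in df.columns:
            raise ValueError("records have no 'region' column")
        df = df[df["region"] == region]
        if df.empty:
            raise ValueError(f"no records for region {region!r}")
    if col not in df.columns:
        raise ValueError(f"records missing endpoint column {col!r}")

    fit = fit_random_intercept(df[col], df["group"], df["mouse_id"])
    levels = set(fit.group_levels)
    use_pairs = [p for p in pairs if set(p) <= levels]
    if not use_pairs:
        from itertools import combinations
        use_pairs = list(combinations(fit.group_levels, 2))

    if fit.p_value < alpha:
        contrasts = posthoc_contrasts(
            fit, group_pairwise_contrasts(fit, use_pairs), adjust=adjust
        )
    else:
        contrasts = pd.DataFrame(
            columns=["contrast", "estimate", "se", "ci_lower", "ci_upper",
                     "p_raw", "p_adjusted"]
        )
    return MorphoResult(endpoint=endpoint, region=region, fit=fit,
                        global_p=fit.p_value, contrasts=contrasts)
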