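"""Supervised PCA of learning.

The analysis is "supervised" in the discriminant-analysis sense: the PCA
is fitted on the small matrix of group-by-session medians of the seven
behavioural variables (e.g. 4 groups x 5 acquisition sessions = 20 rows),
scaled to unit variance, and the individual mouse-session records are
projected into that space afterwards as supplementary points that do not
influence the axes.  Group separation on PC1 is tested by refitting the
entire analysis under random reassignments of mice to groups, and axis
stability by leave-one-mouse-out jackknifing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .metrics import METRIC_VARIABLES

__all__ = [
    "GroupMedianMatrix",
    "PCAModel",
    "build_median_matrix",
    "fit_group_pca",
    "project_individuals",
    "within_group_variance",
    "within_group_variance_table",
    "between_group_variance",
    "jackknife_stability",
    "permutation_test",
]

logger = logging.getLogger(__name__)

def _pc_cols(p: int) -> list[str]:
    return [f"PC{i + 1}" for i in range(p)]


def _proj_cols(proj: pd.DataFrame) -> list[str]:
    return [c for c in proj.columns if c.startswith("PC")]

#: Orientation anchors: PC1 is signed so that the Whishaw-index loading is
#: non-negative (large PC1 = efficient, direct navigation) and PC2 so that
#: the swimming-speed loading is non-negative.
_ORIENT = {0: "whishaw_pct", 1: "mean_speed"}


@dataclass
class GroupMedianMatrix:
    """Group-by-session medians with the standardisation used to fit and
    to project into the PCA space."""

    values: pd.DataFrame          # rows = (group, session), cols = variables
    groups: list[str]
    sessions: list[int]
    center: np.ndarray            # per-variable mean over the rows
    scale: np.ndarray             # per-variable sd over the rows (ddof=0)

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def standardized(self) -> np.ndarray:
        return (self.values.to_numpy() - self.center) / self.scale


@dataclass
class PCAModel:
    """Loadings, eigenvalues and variable contributions of the median PCA."""

    loadings: pd.DataFrame        # variables x components, orthonormal
    eigenvalues: np.ndarray       # non-increasing, sum = n variables
    pct_explained: np.ndarray     # percent of between-group variance
    contributions: pd.DataFrame   # percent, each column sums to 100
    orientation: dict[int, int]   # component -> applied sign
    rank: int


def _session_table(df: pd.DataFrame, phase: str | None, variables) -> pd.DataFrame:
    need = {"mouse_id", "group", "session", *variables}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    if phase is not None:
        if "phase" not in df.columns:
            raise ValueError("metric table has no 'phase' column")
        df = df[df["phase"] == phase]
    if df.empty:
        raise ValueError("no records for the requested phase")
    return df


def build_median_matrix(
    session_df: pd.DataFrame,
    phase: str | None = "ACQ",
    variables=METRIC_VARIABLES,
) -> GroupMedianMatrix:
    """Build the group-by-session median matrix and its standardisation.

    Cell (g, s) holds the median over mice of the session-averaged
    variable.  Each variable is then centred and scaled to unit variance
    using the mean and standard deviation over the matrix rows; the
    center/scale pair is stored for supplementary projection.  Group order
    follows first appearance; rows are group-major.
    """
    df = _session_table(session_df, phase, variables)
    groups = list(pd.unique(df["group"]))
    sessions = sorted(pd.unique(df["session"]))
    rows, labels = [], []
    for g in groups:
        for s in sessions:
            cell = df[(df["group"] == g) & (df["session"] == s)]
            if cell.empty:
                raise ValueError(f"empty cell: group {g!r}, session {s}")
            rows.append(cell[list(variables)].median(axis=0).to_numpy())
            labels.append((g, s))
    values = pd.DataFrame(
        rows, columns=list(variables),
        index=pd.MultiIndex.from_tuples(labels, names=["group", "session"]),
    )
    center = values.to_numpy().mean(axis=0)
    scale = values.to_numpy().std(axis=0)  # ddof=0: unit-variance scaling
    zero = scale <= 0
    if zero.any():
        bad = [v for v, z in zip(variables, zero) if z]
        raise ValueError(f"zero-variance variables in median matrix: {bad}")
    return GroupMedianMatrix(values=values, groups=groups, sessions=sessions,
                             center=center, scale=scale)


def _orient(vectors: np.ndarray, variables: list[str]) -> tuple[np.ndarray, dict[int, int]]:
    signs: dict[int, int] = {}
    for k in range(vectors.shape[1]):
        anchor = _ORIENT.get(k)
        if anchor is not None and abs(vectors[variables.index(anchor), k]) > 1e-12:
            s = 1 if vectors[variables.index(anchor), k] >= 0 else -1
        else:
            lead = int(np.argmax(np.abs(vectors[:, k])))
            s = 1 if vectors[lead, k] >= 0 else -1
        vectors[:, k] *= s
        signs[k] = s
    return vectors, signs


def fit_group_pca(matrix: GroupMedianMatrix) -> PCAModel:
    """Eigen-decomposition of the covariance of the standardised median
    rows.  With unit-variance scaling the eigenvalues sum to the number of
    variables; the contribution of variable v to component k is
    100 * loading_{v,k}^2.
    """
    Z = matrix.standardized
    n = Z.shape[0]
    C = Z.T @ Z / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    evecs, signs = _orient(evecs, matrix.variables)
    total = float(evals.sum())
    pct = 100.0 * evals / total
    contrib = 100.0 * evecs**2 / np.sum(evecs**2, axis=0)
    rank = int(np.sum(evals > 1e-10 * total))
    cols = _pc_cols(len(matrix.variables))
    return PCAModel(
        loadings=pd.DataFrame(evecs, index=matrix.variables, columns=cols),
        eigenvalues=evals,
        pct_explained=pct,
        contributions=pd.DataFrame(contrib, index=matrix.variables, columns=cols),
        orientation=signs,
        rank=rank,
    )


def project_individuals(
    model: PCAModel,
    matrix: GroupMedianMatrix,
    session_df: pd.DataFrame,
    phase: str | None = None,
) -> pd.DataFrame:
    """Project mouse-session records as supplementary points.

    Each record is standardised with the median matrix's stored
    center/scale and multiplied onto the loadings; all component axes are
    retained, so the projection is an isometry of the standardised space.
    """
    variables = matrix.variables
    if list(model.loadings.index) != variables:
        raise ValueError("model and matrix variable order mismatch")
    df = _session_table(session_df, phase, variables)
    Z = (df[variables].to_numpy(dtype=float) - matrix.center) / matrix.scale
    coords = Z @ model.loadings.to_numpy()
    out = df[["mouse_id", "group", "session"]].reset_index(drop=True)
    return pd.concat(
        [out, pd.DataFrame(coords, columns=list(model.loadings.columns))], axis=1)


def _cell(proj: pd.DataFrame, group: str, session) -> np.ndarray:
    cell = proj[(proj["group"] == group) & (proj["session"] == session)]
    if cell.empty:
        raise ValueError(f"no supplementary points for group {group!r}, session {session}")
    return cell[_proj_cols(proj)].to_numpy()


def within_group_variance(proj: pd.DataFrame, group: str, session) -> float:
    """Mean squared distance of a cell's supplementary points from their
    barycentre over all seven axes, scaled by the number of variables:
    (sum_i ||x_i - bar||^2) / n / 7."""
    X = _cell(proj, group, session)
    bar = X.mean(axis=0)
    return float(np.sum((X - bar) ** 2) / X.shape[0] / X.shape[1])


def within_group_variance_table(proj: pd.DataFrame) -> pd.DataFrame:
    """Within-group variance for every (session, group) cell."""
    rows = []
    for s in sorted(pd.unique(proj["session"])):
        for g in pd.unique(proj["group"]):
            rows.append(dict(session=s, group=g,
                             within_variance=within_group_variance(proj, g, s)))
    return pd.DataFrame(rows)


def between_group_variance(proj: pd.DataFrame, matrix: GroupMedianMatrix,
                           model: PCAModel | None = None) -> dict:
    """Between-group variance, two variants, and the decomposition closure.

    Variant (a): variance of the group-session medians about the origin of
    the median-PCA space (the median barycentre).  Variant (b): classical
    between-group variance of the supplementary points — group-session
    cell means about the overall barycentre, weighted by cell size — which
    together with the weighted mean within-cell variance reconstructs the
    total variance of the supplementary points exactly.
    """
    p = len(matrix.variables)
    Z = matrix.standardized
    between_medians = float(np.sum(Z**2) / Z.shape[0] / p)

    X = proj[_proj_cols(proj)].to_numpy()
    bar = X.mean(axis=0)
    total = float(np.sum((X - bar) ** 2) / X.shape[0] / p)
    between_b = 0.0
    within_w = 0.0
    n_total = X.shape[0]
    for (g, s), cell in proj.groupby(["group", "session"], sort=False):
        x = cell[_proj_cols(proj)].to_numpy()
        m = x.mean(axis=0)
        between_b += x.shape[0] * float(np.sum((m - bar) ** 2))
        within_w += float(np.sum((x - m) ** 2))
    between_b /= n_total * p
    within_w /= n_total * p
    rel = abs(between_medians - between_b) / between_b if between_b > 0 else np.nan
    return dict(
        between_medians_origin=between_medians,
        between_classical=between_b,
        within_weighted=within_w,
        total=total,
        closure_error=abs(between_b + within_w - total),
        relative_difference=rel,
    )


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    c = abs(float(a @ b)) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def jackknife_stability(session_df: pd.DataFrame, phase: str | None = "ACQ",
                        variables=METRIC_VARIABLES) -> pd.DataFrame:
    """Leave-one-mouse-out stability of the principal axes.

    For each mouse the median matrix is rebuilt without it, the PCA is
    refitted, and the angle (degrees, sign-aligned) between the new and
    original PC1 and PC2 is recorded.  A deletion that would empty a
    (group, session) cell skips that mouse with a logged warning.
    """
    df = _session_table(session_df, phase, variables)
    base = build_median_matrix(df, phase=None, variables=variables)
    model = fit_group_pca(base)
    v1 = model.loadings["PC1"].to_numpy()
    v2 = model.loadings["PC2"].to_numpy()
    rows = []
    for mouse in pd.unique(df["mouse_id"]):
        sub = df[df["mouse_id"] != mouse]
        try:
            mm = build_median_matrix(sub, phase=None, variables=variables)
        except ValueError as exc:
            logger.warning("jackknife: skipping %s (%s)", mouse, exc)
            continue
        if mm.groups != base.groups or mm.sessions != base.sessions:
            logger.warning("jackknife: skipping %s (deletion empties a cell)", mouse)
            continue
        m = fit_group_pca(mm)
        rows.append(dict(
            mouse_id=mouse,
            angle_pc1=_angle_deg(m.loadings["PC1"].to_numpy(), v1),
            angle_pc2=_angle_deg(m.loadings["PC2"].to_numpy(), v2),
        ))
    return pd.DataFrame(rows, columns=["mouse_id", "angle_pc1", "angle_pc2"])


# ---------------------------------------------------------------------------
# Permutation test on PC1 — fast array core
# ---------------------------------------------------------------------------

def _pivot(df: pd.DataFrame, variables) -> tuple[np.ndarray, np.ndarray, list[str], list[int], list[str]]:
    """(n_mice, n_sessions, p) array plus group codes, in first-appearance
    group order and sorted session order."""
    mice = list(pd.unique(df["mouse_id"]))
    sessions = sorted(pd.unique(df["session"]))
    groups = list(pd.unique(df["group"]))
    gmap = {m: g for m, g in zip(df["mouse_id"], df["group"])}
    codes = np.array([groups.index(gmap[m]) for m in mice])
    wide = df.set_index(["mouse_id", "session"])
    X = np.empty((len(mice), len(sessions), len(variables)))
    for i, m in enumerate(mice):
        for j, s in enumerate(sessions):
            try:
                X[i, j] = wide.loc[(m, s), list(variables)].to_numpy(dtype=float)
            except KeyError:
                raise ValueError(f"mouse {m!r} missing session {s}") from None
    return X, codes, mice, sessions, groups


def _pc1_scores(X: np.ndarray, codes: np.ndarray, n_groups: int,
                whishaw_idx: int) -> np.ndarray:
    """Refit the whole median PCA for a group assignment and return the
    supplementary PC1 coordinates, shape (n_mice, n_sessions)."""
    med = np.stack([np.median(X[codes == g], axis=0) for g in range(n_groups)])
    M = med.reshape(-1, X.shape[2])
    c = M.mean(axis=0)
    sd = M.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (M - c) / sd
    C = Z.T @ Z / Z.shape[0]
    _, vecs = np.linalg.eigh(C)
    v1 = vecs[:, -1]
    if v1[whishaw_idx] < 0:
        v1 = -v1
    return ((X - c) / sd) @ v1


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float((a.mean() - b.mean()) / denom)


def permutation_test(
    session_df: pd.DataFrame,
    phase: str | None = "ACQ",
    sessions_of_interest=None,
    n_permutations: int = 10_000,
    seed: int = 0,
    variables=METRIC_VARIABLES,
) -> pd.DataFrame:
    """Permutation test of pairwise group separation on PC1.

    The observed statistic per (session, group pair) is the Welch
    (unpooled) pseudo-t on the supplementary PC1 coordinates.  Each
    permutation reassigns mice to groups at random with the original group
    sizes kept, rebuilds the median matrix, refits the PCA (same
    orientation rule), reprojects, and recomputes every pairwise
    statistic; the two-sided p-value is (1 + #{|t*| >= |t_obs|}) / (1 + N).
    By default the first and last sessions of the phase are tested.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    df = _session_table(session_df, phase, variables)
    X, codes, mice, sessions, groups = _pivot(df, variables)
    G = len(groups)
    if G < 2:
        raise ValueError("at least two groups required")
    sizes = np.bincount(codes, minlength=G)
    if (sizes < 2).any():
        small = [groups[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"groups of size < 2 have undefined pseudo-t: {small}")
    if sessions_of_interest is None:
        sessions_of_interest = [sessions[0], sessions[-1]]
    s_idx = []
    for s in sessions_of_interest:
        if s not in sessions:
            raise ValueError(f"session {s} not present")
        s_idx.append(sessions.index(s))
    wh = list(variables).index("whishaw_pct") if "whishaw_pct" in variables else 0
    pairs = list(combinations(range(G), 2))

    def stats_for(assign: np.ndarray) -> np.ndarray:
        pc1 = _pc1_scores(X, assign, G, wh)
        out = np.empty((len(s_idx), len(pairs)))
        for i, sj in enumerate(s_idx):
            col = pc1[:, sj]
            for j, (a, b) in enumerate(pairs):
                out[i, j] = _welch_t(col[assign == a], col[assign == b])
        return out

    t_obs = stats_for(codes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(t_obs)
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        t_perm = stats_for(perm)
        exceed += np.abs(t_perm) >= np.abs(t_obs)
    pvals = (1.0 + exceed) / (1.0 + n_permutations)

    rows = []
    for i, s in enumerate(sessions_of_interest):
        for j, (a, b) in enumerate(pairs):
            rows.append(dict(
                session=s, group_a=groups[a], group_b=groups[b],
                pseudo_t=t_obs[i, j], p_value=pvals[i, j],
                n_permutations=n_permutations, seed=seed,
            ))
    return pd.DataFrame(rows)
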