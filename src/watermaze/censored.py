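"""Single-variate inference: right-censored (Tobit) regression,
random-intercept mixed models, Wald contrasts and multiplicity control.

The Tobit model assumes a latent Gaussian response observed only up to a
fixed right-censoring bound (here the 60 s trial limit); the likelihood
combines normal densities for observed values with upper-tail
probabilities for censored ones and is maximised by quasi-Newton descent
from the censoring-ignorant least-squares start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "TobitFit",
    "MixedFit",
    "fit_tobit",
    "fit_random_intercept",
    "posthoc_contrasts",
    "group_pairwise_contrasts",
    "benjamini_hochberg",
    "holm",
    "latency_group_test",
]

_GTOL = 1e-8


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    adjusted_(i) = min_{j >= i} m * p_(j) / j, capped at 1, with the
    original order restored; ties share the same adjusted value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def holm(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * (m - np.arange(m))
    adjusted = np.maximum.accumulate(ranked)
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class TobitFit:
    """Right-censored Gaussian MLE."""

    params: pd.Series            # regression coefficients
    sigma: float                 # error scale
    bse: pd.Series               # standard errors of the coefficients
    sigma_se: float
    cov: pd.DataFrame            # covariance of the coefficients
    loglik: float
    loglik_null: float           # intercept-only censored model
    chi2: float                  # LR statistic vs intercept-only
    df: int
    converged: bool
    n_obs: int
    n_censored: int
    bound: float

    @property
    def chi2_pvalue(self) -> float:
        return float(stats.chi2.sf(self.chi2, self.df)) if self.df > 0 else np.nan

    def loglikelihood(self, params=None, sigma=None) -> float:
        """Censored log-likelihood at arbitrary parameter values."""
        b = self.params.to_numpy() if params is None else np.asarray(params, float)
        s = self.sigma if sigma is None else float(sigma)
        return _tobit_loglik(self._y, self._cens, self._X, self.bound, b, s)

    # raw data retained for likelihood evaluation / diagnostics
    _y: np.ndarray = field(default=None, repr=False)
    _cens: np.ndarray = field(default=None, repr=False)
    _X: np.ndarray = field(default=None, repr=False)


def _tobit_loglik(y, cens, X, bound, beta, sigma) -> float:
    if sigma <= 0:
        return -np.inf
    xb = X @ beta
    ll = 0.0
    obs = ~cens
    r = (y[obs] - xb[obs]) / sigma
    ll += float(np.sum(stats.norm.logpdf(r) - np.log(sigma)))
    if cens.any():
        z = (bound - xb[cens]) / sigma
        ll += float(np.sum(stats.norm.logsf(z)))
    return ll


def fit_tobit(y, censored, X, bound: float = 60.0) -> TobitFit:
    """Maximum-likelihood fit of the right-censored normal regression.

    ``X`` may be a DataFrame (column names become coefficient names) or a
    2-D array.  Requires at least one uncensored observation and a
    full-rank design.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i}" for i in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float)
    cens = np.asarray(censored, dtype=bool)
    if y.shape[0] != Xm.shape[0] or cens.shape[0] != y.shape[0]:
        raise ValueError("y, censored and X must have matching lengths")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(Xm)):
        raise ValueError("non-finite values in response or design")
    if cens.all():
        raise ValueError("all observations censored; model not identifiable")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("design matrix is rank deficient")

    obs = ~cens
    beta0, *_ = np.linalg.lstsq(Xm[obs], y[obs], rcond=None)
    resid = y[obs] - Xm[obs] @ beta0
    s0 = float(np.sqrt(np.mean(resid**2)))
    s0 = max(s0, 1e-3 * max(1.0, float(np.std(y)) or 1.0))
    theta0 = np.concatenate([beta0, [np.log(s0)]])

    def negll(theta):
        return -_tobit_loglik(y, cens, Xm, bound, theta[:-1], np.exp(theta[-1]))

    def grad(theta):
        b, s = theta[:-1], np.exp(theta[-1])
        xb = Xm @ b
        g_b = np.zeros_like(b)
        g_ls = 0.0
        r = (y[obs] - xb[obs]) / s
        g_b += Xm[obs].T @ r / s
        g_ls += float(np.sum(r**2 - 1.0))
        if cens.any():
            z = (bound - xb[cens]) / s
            lam = np.exp(stats.norm.logpdf(z) - stats.norm.logsf(z))
            g_b += Xm[cens].T @ lam / s
            g_ls += float(np.sum(lam * z))
        return -np.concatenate([g_b, [g_ls]])

    res = optimize.minimize(negll, theta0, jac=grad, method="BFGS",
                            options={"gtol": _GTOL, "maxiter": 500})
    converged = bool(res.success or np.max(np.abs(res.jac)) < 1e-5)
    if not converged:
        raise RuntimeError(f"tobit optimisation did not converge: {res.message}")
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))

    # Observed information on the natural (beta, sigma) scale.
    def negll_nat(theta):
        return -_tobit_loglik(y, cens, Xm, bound, theta[:-1], theta[-1])

    H = approx_hess1(np.concatenate([beta, [sigma]]), negll_nat)
    cov_all = np.linalg.inv(H)
    se_all = np.sqrt(np.clip(np.diag(cov_all), 0.0, None))

    k = len(beta)
    if k > 1:
        null = fit_tobit(y, cens, np.ones((len(y), 1)), bound)
        ll0 = null.loglik
    else:
        ll0 = -res.fun
    ll = -float(res.fun)
    chi2 = max(0.0, 2.0 * (ll - ll0))

    fit = TobitFit(
        params=pd.Series(beta, index=names),
        sigma=sigma,
        bse=pd.Series(se_all[:k], index=names),
        sigma_se=float(se_all[k]),
        cov=pd.DataFrame(cov_all[:k, :k], index=names, columns=names),
        loglik=ll,
        loglik_null=ll0,
        chi2=chi2,
        df=k - 1,
        converged=converged,
        n_obs=len(y),
        n_censored=int(cens.sum()),
        bound=float(bound),
    )
    fit._y, fit._cens, fit._X = y, cens, Xm
    return fit


@dataclass
class MixedFit:
    """Gaussian random-intercept fit (group fixed factor, mouse random)."""

    params: pd.Series
    cov: pd.DataFrame
    bse: pd.Series
    between_var: float
    resid_var: float
    fvalue: float
    df_num: int
    df_den: int
    p_value: float
    group_levels: list[str]
    n_mice: int
    n_obs: int
    method: str  # "reml" or "ols" (one observation per mouse)
    converged: bool = True


def _group_design(groups: pd.Series) -> tuple[pd.DataFrame, list[str]]:
    levels = list(pd.unique(groups))
    X = pd.DataFrame({"Intercept": np.ones(len(groups))})
    for lv in levels[1:]:
        X[f"group[{lv}]"] = (groups == lv).astype(float).to_numpy()
    return X, levels


def fit_random_intercept(values, groups, mice) -> MixedFit:
    """REML fit of value ~ group with a per-mouse random intercept.

    The global test of the group factor is a Wald F with between-mouse
    denominator degrees of freedom (n_mice - n_groups).  When every mouse
    contributes a single value the random intercept is unidentifiable and
    the model collapses to ordinary one-way ANOVA, fitted by OLS.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "group": np.asarray(groups, dtype=object),
        "mouse": np.asarray(mice, dtype=object),
    })
    if df["value"].isna().any():
        raise ValueError("missing values in response")
    per_mouse = df.groupby("mouse")["group"].nunique()
    if (per_mouse > 1).any():
        bad = per_mouse[per_mouse > 1].index.tolist()
        raise ValueError(f"mice assigned to multiple groups: {bad}")
    X, levels = _group_design(df["group"])
    G = len(levels)
    if G < 2:
        raise ValueError("at least two groups required")
    mice_per_group = df.groupby("group")["mouse"].nunique()
    if (mice_per_group < 2).any():
        raise ValueError("each group needs at least two mice")
    n_mice = df["mouse"].nunique()
    q = G - 1
    df_den = n_mice - G

    one_per_mouse = df.groupby("mouse").size().max() == 1
    if one_per_mouse:
        ols = sm.OLS(df["value"].to_numpy(), X.to_numpy()).fit()
        params = pd.Series(ols.params, index=X.columns)
        cov = pd.DataFrame(ols.cov_params(), index=X.columns, columns=X.columns)
        between_var, resid_var = 0.0, float(ols.scale)
        converged = True
        method = "ols"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df["value"].to_numpy(), X.to_numpy(),
                               groups=df["mouse"].to_numpy())
            result = model.fit(reml=True)
        k = X.shape[1]
        params = pd.Series(result.fe_params, index=X.columns)
        cov = pd.DataFrame(np.asarray(result.cov_params())[:k, :k],
                           index=X.columns, columns=X.columns)
        between_var = float(np.asarray(result.cov_re).ravel()[0])
        resid_var = float(result.scale)
        converged = bool(result.converged)
        method = "reml"

    # Wald F for the group factor.
    sel = [i for i, c in enumerate(X.columns) if c.startswith("group[")]
    L = np.zeros((q, X.shape[1]))
    for r, i in enumerate(sel):
        L[r, i] = 1.0
    cb = L @ params.to_numpy()
    V = L @ cov.to_numpy() @ L.T
    fvalue = float(cb @ np.linalg.solve(V, cb) / q)
    p_value = float(stats.f.sf(fvalue, q, df_den)) if df_den > 0 else np.nan

    return MixedFit(
        params=params,
        cov=cov,
        bse=pd.Series(np.sqrt(np.diag(cov.to_numpy())), index=X.columns),
        between_var=between_var,
        resid_var=resid_var,
        fvalue=fvalue,
        df_num=q,
        df_den=df_den,
        p_value=p_value,
        group_levels=levels,
        n_mice=n_mice,
        n_obs=len(df),
        method=method,
        converged=converged,
    )


def _contrast_vector(fit, spec) -> np.ndarray:
    names = list(fit.params.index)
    if isinstance(spec, dict):
        vec = np.zeros(len(names))
        for name, coef in spec.items():
            if name not in names:
                raise ValueError(f"contrast references absent coefficient {name!r}")
            vec[names.index(name)] = coef
        return vec
    vec = np.asarray(spec, dtype=float)
    if vec.shape != (len(names),):
        raise ValueError("contrast vector length does not match coefficients")
    return vec


def posthoc_contrasts(fit, contrasts: dict, adjust: str = "bh",
                      conf_level: float = 0.95) -> pd.DataFrame:
    """Wald contrasts of fitted coefficients with multiplicity adjustment.

    ``contrasts`` maps a label to either a coefficient-name -> weight dict
    or a full-length vector.  Normal-approximation CIs and two-sided
    p-values; the family is adjusted by Benjamini–Hochberg (``"bh"``,
    false-discovery-rate control) or Holm (``"holm"``, family-wise).
    """
    if adjust not in ("bh", "holm", "none"):
        raise ValueError("adjust must be 'bh', 'holm' or 'none'")
    cols = ["contrast", "estimate", "se", "ci_lower", "ci_upper", "p_raw", "p_adjusted"]
    if not contrasts:
        return pd.DataFrame(columns=cols)
    beta = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    zq = stats.norm.ppf(0.5 + conf_level / 2.0)
    rows = []
    for label, spec in contrasts.items():
        c = _contrast_vector(fit, spec)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        z = est / se if se > 0 else np.inf * np.sign(est)
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append(dict(contrast=label, estimate=est, se=se,
                         ci_lower=est - zq * se, ci_upper=est + zq * se,
                         p_raw=p))
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adjusted"] = benjamini_hochberg(out["p_raw"].to_numpy())
    elif adjust == "holm":
        out["p_adjusted"] = holm(out["p_raw"].to_numpy())
    else:
        out["p_adjusted"] = out["p_raw"]
    return out


def group_pairwise_contrasts(fit, pairs: list[tuple[str, str]]) -> dict:
    """Build ``a - b`` contrast dicts from the dummy coding of a fit whose
    design is Intercept + group[level] columns (reference = first level)."""
    levels = getattr(fit, "group_levels", None)
    contrasts = {}
    for a, b in pairs:
        if levels is not None and (a not in levels or b not in levels):
            raise ValueError(f"unknown group in contrast {a}_{b}")
        spec: dict[str, float] = {}
        for lv, sign in ((a, 1.0), (b, -1.0)):
            name = f"group[{lv}]"
            if name in fit.params.index:
                spec[name] = spec.get(name, 0.0) + sign
            elif levels is not None and lv == levels[0]:
                pass  # reference level: zero contribution
            else:
                raise ValueError(f"contrast references absent coefficient {name!r}")
        contrasts[f"{a}_{b}"] = spec
    return contrasts


def latency_group_test(session_df: pd.DataFrame, bound: float = 60.0,
                       value: str = "latency") -> tuple[TobitFit, dict]:
    """Censored-latency group analysis on session-averaged data.

    Fits ``latency ~ group + session`` (both as factors) by Tobit MLE — a
    session mean is censored only when every trial of the session was —
    and reports the likelihood-ratio test of the group factor (df =
    n_groups - 1) against the session-only model.
    """
    need = {"mouse_id", "group", "session", value}
    if not need.issubset(session_df.columns):
        raise ValueError(f"session table missing {sorted(need - set(session_df.columns))}")
    y = session_df[value].to_numpy(dtype=float)
    if "censored" in session_df.columns:
        cens = session_df["censored"].to_numpy(dtype=bool)
    else:
        cens = y >= bound - 1e-9
    Xg, levels = _group_design(session_df["group"])
    X = Xg.copy()
    sessions = list(pd.unique(session_df["session"]))
    for s in sessions[1:]:
        X[f"session[{s}]"] = (session_df["session"] == s).astype(float).to_numpy()
    full = fit_tobit(y, cens, X, bound)
    full.group_levels = levels  # type: ignore[attr-defined]
    reduced = fit_tobit(y, cens, X.drop(columns=[c for c in X if c.startswith("group[")]), bound)
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = len(levels) - 1
    return full, dict(chi2=chi2, df=df,
                      p_value=float(stats.chi2.sf(chi2, df)),
                      loglik_full=full.loglik, loglik_reduced=reduced.loglik)
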