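"""Penalized quasi-likelihood GLMMs with a single random intercept.

The paired field design needs only one random effect (the burnt/unburnt plot
pair), so the mixed models are fitted by classic PQL: iterate the GLM working
response and weights, and at each step fit the weighted linear mixed model by
REML, profiling the variance ratio ``theta = tau^2 / sigma^2`` with a
closed-form (Woodbury) per-group inverse. Supported conditional families are
Poisson (log link, for richness counts) and beta (logit link with a
moment-estimated precision, for evenness on (0,1)).

If PQL fails to converge the model falls back to a fixed-effects fit with
pair indicators, flagged in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

from .errors import DegenerateFitError, InvalidDesignError

_MAX_OUTER = 100
_BETA_EPS = 1e-8


@dataclass
class GLMMFit:
    params: pd.Series
    cov_params: pd.DataFrame
    tests: pd.DataFrame          # Type-III Wald chi-square per term
    sigma2: float
    tau2: float
    phi: float | None
    family: str
    converged: bool
    method: str = "pql"          # pql | fixed-fallback
    notes: list = field(default_factory=list)


def _weighted_lmm_reml(z, X, groups, w):
    """REML fit of z = X b + u_group + e with per-observation weights.

    Var(e_i) = sigma^2 / w_i, u ~ N(0, tau^2). Returns (beta, cov_beta,
    sigma2, tau2, blup_per_group).
    """
    n, p = X.shape
    glabels, ginv = np.unique(groups, return_inverse=True)
    gsets = [np.flatnonzero(ginv == k) for k in range(len(glabels))]

    def _assemble(theta):
        XtMX = np.zeros((p, p))
        XtMz = np.zeros(p)
        zMz = 0.0
        logdet = 0.0
        for idx in gsets:
            wg = w[idx]
            Xg = X[idx]
            zg = z[idx]
            sw = wg.sum()
            denom = 1.0 / theta + sw if theta > 0 else np.inf
            # M = diag(w) - w w' / (1/theta + sum w)
            Xw = Xg * wg[:, None]
            zw = zg * wg
            XtMX_g = Xg.T @ Xw
            XtMz_g = Xg.T @ zw
            zMz_g = zg @ zw
            if np.isfinite(denom):
                a = Xw.sum(axis=0)
                b = zw.sum()
                XtMX_g -= np.outer(a, a) / denom
                XtMz_g -= a * b / denom
                zMz_g -= b * b / denom
                logdet += np.log1p(theta * sw)
            logdet += -np.log(wg).sum()
            XtMX += XtMX_g
            XtMz += XtMz_g
            zMz += zMz_g
        return XtMX, XtMz, zMz, logdet

    def _neg_reml(log_theta):
        theta = np.exp(log_theta)
        XtMX, XtMz, zMz, logdet = _assemble(theta)
        try:
            beta = np.linalg.solve(XtMX, XtMz)
        except np.linalg.LinAlgError:
            return np.inf
        q = max(zMz - beta @ XtMz, 1e-300)
        sign, ld_xmx = np.linalg.slogdet(XtMX)
        if sign <= 0:
            return np.inf
        return (n - p) * np.log(q / (n - p)) + logdet + ld_xmx

    res = optimize.minimize_scalar(_neg_reml, bounds=(-14.0, 10.0), method="bounded")
    theta = float(np.exp(res.x))
    if _neg_reml(-20.0) <= res.fun:  # boundary: no pair variance
        theta = 0.0
    XtMX, XtMz, zMz, _ = _assemble(theta)
    beta = np.linalg.solve(XtMX, XtMz)
    q = max(zMz - beta @ XtMz, 1e-300)
    sigma2 = q / (n - p)
    cov = sigma2 * np.linalg.inv(XtMX)
    blup = {}
    for k, idx in enumerate(gsets):
        r = z[idx] - X[idx] @ beta
        sw = w[idx].sum()
        blup[glabels[k]] = theta * (w[idx] * r).sum() / (1.0 + theta * sw) if theta > 0 else 0.0
    return beta, cov, sigma2, theta * sigma2, blup, ginv, glabels


def fit_glmm_pql(
    y,
    metadata: pd.DataFrame,
    family: str,
    formula: str = "C(fire, Sum) * C(substrate, Sum)",
    group_col: str = "pair",
):
    """PQL GLMM of ``y`` on the treatment design with a pair random intercept."""
    meta = metadata.reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    if group_col not in meta.columns:
        raise InvalidDesignError(f"metadata lacks the {group_col!r} pairing column")
    if meta[group_col].value_counts().max() < 2:
        raise InvalidDesignError("design is unpaired: every pair has a single sample")
    X_dm = patsy.dmatrix(formula, meta, return_type="dataframe")
    X = np.asarray(X_dm)
    names = list(X_dm.columns)
    groups = meta[group_col].to_numpy()
    n, p = X.shape

    if family == "poisson":
        if np.any(y < 0):
            raise ValueError("Poisson response must be nonnegative")
        if np.ptp(y) == 0.0:
            return _constant_fit(y, X_dm, family, link="log")
        mu = np.clip(y, 0.5, None)
        eta = np.log(mu)
        phi = None
    elif family == "beta":
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("beta response must lie strictly in (0, 1)")
        if np.ptp(y) == 0.0:
            raise DegenerateFitError("constant response: beta fit impossible")
        mu = np.clip(y, 1e-3, 1 - 1e-3)
        eta = np.log(mu / (1 - mu))
        phi = 10.0
    else:
        raise ValueError(f"unknown family {family!r}")

    beta_old = None
    converged = False
    offset = np.zeros(n)
    for _ in range(_MAX_OUTER):
        if family == "poisson":
            dmu = mu
            V = mu
        else:
            dmu = mu * (1 - mu)
            V = mu * (1 - mu) / (1 + phi)
        w = dmu**2 / V
        z = eta + (y - mu) / dmu
        beta, cov, sigma2, tau2, blup, ginv, glabels = _weighted_lmm_reml(z, X, groups, w)
        u = np.array([blup[g] for g in groups])
        eta = X @ beta + u
        if family == "poisson":
            mu = np.clip(np.exp(eta), 1e-10, 1e12)
        else:
            mu = np.clip(1 / (1 + np.exp(-eta)), 1e-8, 1 - 1e-8)
            resid = np.sum((y - mu) ** 2 / (mu * (1 - mu)))
            phi = max((n - p) / max(resid, 1e-12) - 1.0, 1e-6)
        if beta_old is not None and np.max(np.abs(beta - beta_old)) < _BETA_EPS * (
            1 + np.max(np.abs(beta))
        ):
            converged = True
            break
        beta_old = beta

    if not converged:
        return _fixed_fallback(y, meta, family, formula, group_col)

    params = pd.Series(beta, index=names)
    covd = pd.DataFrame(cov, index=names, columns=names)
    tests = _wald_type3(params, covd, X_dm.design_info)
    return GLMMFit(params, covd, tests, sigma2, tau2, phi, family, True, "pql")


def _pretty_term(term: str) -> str:
    import re

    return re.sub(r"C\((\w+)[^)]*\)", r"\1", term)


def _wald_type3(params: pd.Series, cov: pd.DataFrame, design_info) -> pd.DataFrame:
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        b = params.iloc[sl].to_numpy()
        C = cov.iloc[sl, sl].to_numpy()
        df = len(b)
        try:
            chi2 = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError:
            chi2 = np.nan
        pval = float(stats.chi2.sf(chi2, df)) if np.isfinite(chi2) else np.nan
        rows.append({"effect": _pretty_term(term), "chi2": chi2, "df": df, "p": pval})
    return pd.DataFrame(rows).set_index("effect")


def _constant_fit(y, X_dm, family, link):
    names = list(X_dm.columns)
    params = pd.Series(0.0, index=names)
    params.iloc[0] = np.log(y[0]) if link == "log" else 0.0
    cov_arr = np.zeros((len(names), len(names)))
    np.fill_diagonal(cov_arr, np.inf)
    cov = pd.DataFrame(cov_arr, index=names, columns=names)
    rows = [
        {"effect": _pretty_term(t), "chi2": 0.0,
         "df": len(range(*sl.indices(len(names)))), "p": 1.0}
        for t, sl in X_dm.design_info.term_name_slices.items()
        if t != "Intercept"
    ]
    tests = pd.DataFrame(rows).set_index("effect")
    return GLMMFit(params, cov, tests, 0.0, 0.0, None, family, True, "pql",
                   notes=["constant response; all effects zero"])


def _fixed_fallback(y, meta, family, formula, group_col):
    """Pair-as-fixed-effects GLM when PQL does not converge."""
    import statsmodels.api as sm

    full = f"{formula} + C({group_col})"
    X_dm = patsy.dmatrix(full, meta, return_type="dataframe")
    if family == "poisson":
        res = sm.GLM(y, X_dm, family=sm.families.Poisson()).fit()
        phi = None
    else:
        from statsmodels.othermod.betareg import BetaModel

        res = BetaModel(y, X_dm).fit(disp=False)
        phi = float(np.exp(res.params.iloc[-1]))
    k = X_dm.design_info.term_name_slices
    params = pd.Series(np.asarray(res.params)[: X_dm.shape[1]], index=X_dm.columns)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[: X_dm.shape[1], : X_dm.shape[1]],
        index=X_dm.columns,
        columns=X_dm.columns,
    )
    tests = _wald_type3(params, cov, X_dm.design_info)
    tests = tests[tests.index != group_col]
    return GLMMFit(params, cov, tests, np.nan, np.nan, phi, family, True,
                   "fixed-fallback", notes=["PQL did not converge"])
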