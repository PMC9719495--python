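"""Influential-family selection and Tweedie interaction modelling.

A family is *influential* when its taxon score on the first two constrained
ordination axes lies farther from the origin than the mean distance from the
origin to the four substrate-by-fire group centroids (computed on site scores
in the same, taxon-focused, scaling). Influential families' relative
abundances are then modelled jointly with a log-link Tweedie GLM of the
family x fire x substrate interaction, after a within-family standardization
to mean 1 so that only treatment-versus-treatment patterns within a family
are interpretable. Pairwise treatment ratios per family carry simultaneous
confidence intervals (single-step max-|z| adjustment over the whole contrast
family), and each family is classified as a substrate, fire, or single-cell
specialist from the pattern of standardized cell means and contrast
significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.genmod.families import Tweedie
from statsmodels.genmod.families.links import Log

from ._rng import stage_rng
from .errors import DegenerateFitError, InvalidDesignError
from .simulate import CELLS

POWER_GRID = tuple(np.round(np.arange(1.1, 1.95, 0.1), 1))


# ---------------------------------------------------------------------------
# selection statistic
# ---------------------------------------------------------------------------

def interaction_centroids(ordination_result, metadata: pd.DataFrame, n_axes: int = 2) -> pd.DataFrame:
    """Mean site score per substrate-by-fire cell on the leading axes.

    Site scores are taken in the taxon-focused scaling so centroids and taxon
    scores share one coordinate system.
    """
    scores = ordination_result.site_scores["taxa"]
    if scores.shape[1] < n_axes:
        raise InvalidDesignError(
            f"ordination has {scores.shape[1]} constrained axes; need >= {n_axes}"
        )
    scores = scores.iloc[:, :n_axes]
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    cells = meta.loc[scores.index, "fire"].str.cat(meta.loc[scores.index, "substrate"], sep="-")
    cent = scores.groupby(cells.to_numpy()).mean()
    missing = [c for c in CELLS if c not in cent.index]
    if missing:
        raise InvalidDesignError(f"empty substrate-by-fire cells: {missing}")
    return cent.loc[list(CELLS)]


def influential_threshold(centroids: pd.DataFrame) -> float:
    """Mean Euclidean distance from the origin to the group centroids."""
    C = np.asarray(centroids, dtype=float)
    if C.size == 0:
        raise InvalidDesignError("no centroids supplied")
    return float(np.linalg.norm(C, axis=1).mean())


def select_influential(
    taxon_scores: pd.DataFrame,
    threshold: float,
    mode: str = "distance",
) -> tuple[list, pd.Series]:
    """Families whose score exceeds the centroid threshold.

    ``mode='distance'`` (default) uses the Euclidean distance from the origin
    in the plane of the supplied axes; ``mode='per_axis'`` selects when any
    single |score| exceeds the threshold.
    """
    S = np.asarray(taxon_scores, dtype=float)
    if mode == "distance":
        d = np.linalg.norm(S, axis=1)
    elif mode == "per_axis":
        d = np.abs(S).max(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    dist = pd.Series(d, index=taxon_scores.index, name="origin_distance")
    selected = list(dist.index[dist > threshold])
    return selected, dist


def selection_performance(selected, truth_labels: pd.Series) -> dict:
    """Sensitivity/specificity of the selection against planted ground truth."""
    positive = set(truth_labels.index[truth_labels != "none"])
    negative = set(truth_labels.index[truth_labels == "none"])
    sel = set(selected)
    tp = len(sel & positive)
    tn = len(negative - sel)
    return {
        "sensitivity": tp / len(positive) if positive else np.nan,
        "specificity": tn / len(negative) if negative else np.nan,
        "n_selected": len(sel),
    }


# ---------------------------------------------------------------------------
# Tweedie GLM of the triple interaction
# ---------------------------------------------------------------------------

@dataclass
class TweedieFit:
    result: object                # statsmodels GLMResults
    power: float
    dispersion: float
    cell_means: pd.DataFrame      # families x CELLS, standardized scale
    tests: pd.DataFrame           # Type-III style Wald tests per term
    data: pd.DataFrame            # the long-format standardized data
    families: list
    excluded: list


def within_family_standardize(relabund: pd.DataFrame, families: list) -> tuple[pd.DataFrame, list]:
    """Divide each family's values by its grand mean (standardized mean = 1)."""
    excluded = [f for f in families if relabund[f].mean() <= 0]
    kept = [f for f in families if f not in excluded]
    std = relabund[kept] / relabund[kept].mean(axis=0)
    return std, excluded


def _long_format(std: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    long = std.stack().rename("y").reset_index()
    long.columns = ["sample_id", "family", "y"]
    long["fire"] = meta.loc[long["sample_id"], "fire"].to_numpy()
    long["substrate"] = meta.loc[long["sample_id"], "substrate"].to_numpy()
    return long


def fit_tweedie_interaction(
    relabund: pd.DataFrame,
    metadata: pd.DataFrame,
    families: list,
    power_grid=POWER_GRID,
) -> TweedieFit:
    """Log-link Tweedie GLM of family*fire*substrate on standardized abundances.

    The Tweedie power index is chosen by profiling the series log-likelihood
    over a fixed grid in (1, 2). Families absent from any of the four
    treatment cells are excluded with a warning. Returns coefficient fit,
    Type-III Wald tests, and fitted per-family per-cell means.
    """
    std, excluded = within_family_standardize(relabund, list(families))
    long = _long_format(std, metadata)
    cells = long["fire"].str.cat(long["substrate"], sep="-")

    # presence in every treatment cell at least once
    occupied = (
        long.assign(cell=cells, pos=long["y"] > 0)
        .groupby(["family", "cell"])["pos"]
        .any()
        .groupby("family")
        .all()
    )
    absent = list(occupied.index[~occupied])
    if absent:
        warnings.warn(f"families absent from a treatment cell excluded: {absent}")
        excluded = excluded + absent
        long = long[~long["family"].isin(absent)]
    if long["family"].nunique() == 0:
        raise DegenerateFitError("no families left to fit")
    if float(np.var(long["y"])) == 0.0:
        raise DegenerateFitError("zero-variance response")

    kept = sorted(long["family"].unique())
    formula = (
        "y ~ C(family, Sum)*C(fire, Sum)*C(substrate, Sum)"
        if len(kept) > 1
        else "y ~ C(fire, Sum)*C(substrate, Sum)"
    )

    best = None
    for p in power_grid:
        fam = Tweedie(var_power=float(p), link=Log())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM.from_formula(formula, data=long, family=fam).fit()
        llf = res.llf
        if np.isfinite(llf) and (best is None or llf > best[1]):
            best = (float(p), llf, res)
    if best is None:
        raise DegenerateFitError("Tweedie profile failed on every grid power")
    power, _, res = best

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tests = res.wald_test_terms(scalar=True).table
    tests = tests.rename(columns={"statistic": "F", "pvalue": "p"})

    grid = pd.DataFrame(
        [
            {"family": f, "fire": c.split("-")[0], "substrate": c.split("-")[1]}
            for f in kept
            for c in CELLS
        ]
    )
    grid["mu"] = res.predict(grid)
    cell_means = grid.assign(cell=grid["fire"].str.cat(grid["substrate"], sep="-")).pivot(
        index="family", columns="cell", values="mu"
    )[list(CELLS)]

    return TweedieFit(
        result=res,
        power=power,
        dispersion=float(res.scale),
        cell_means=cell_means,
        tests=tests,
        data=long,
        families=kept,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# simultaneous treatment contrasts
# ---------------------------------------------------------------------------

_PAIRS = [(i, j) for i in range(4) for j in range(i + 1, 4)]


def treatment_contrasts(fit: TweedieFit, alpha: float = 0.05, seed: int = 0, n_draws: int = 20_000) -> pd.DataFrame:
    """All pairwise treatment-mean ratios per family with simultaneous CIs.

    Works on the log scale: each contrast is a difference of cell linear
    predictors; the single-step critical value is the 1-alpha quantile of the
    max-|z| statistic over the whole contrast family, simulated (seeded) from
    the joint normal of the contrast estimates. A contrast is significant when
    its simultaneous interval for the ratio excludes 1.
    """
    res = fit.result
    # design rows for each family x cell
    grid = pd.DataFrame(
        [
            {"family": f, "fire": c.split("-")[0], "substrate": c.split("-")[1]}
            for f in fit.families
            for c in CELLS
        ]
    )
    import patsy

    X = patsy.build_design_matrices([res.model.data.design_info], grid)[0]
    X = np.asarray(X)
    rows = []
    L = []
    for fi, f in enumerate(fit.families):
        block = X[fi * 4 : (fi + 1) * 4]
        for i, j in _PAIRS:
            L.append(block[i] - block[j])
            rows.append({"family": f, "contrast": f"{CELLS[i]} / {CELLS[j]}"})
    L = np.vstack(L)
    beta = np.asarray(res.params)
    covb = np.asarray(res.cov_params())
    est = L @ beta
    cov = L @ covb @ L.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if np.any(se == 0) or not np.all(np.isfinite(se)):
        raise DegenerateFitError("singular covariance in contrast family")

    corr = cov / np.outer(se, se)
    # symmetrize + ridge for numerical PSD
    corr = (corr + corr.T) / 2 + 1e-10 * np.eye(len(se))
    rng = stage_rng(seed, "contrasts")
    Lc = np.linalg.cholesky(corr)
    draws = rng.standard_normal((n_draws, len(se))) @ Lc.T
    crit = float(np.quantile(np.abs(draws).max(axis=1), 1 - alpha))

    out = pd.DataFrame(rows)
    out["log_ratio"] = est
    out["se"] = se
    out["ratio"] = np.exp(est)
    out["lo"] = np.exp(est - crit * se)
    out["hi"] = np.exp(est + crit * se)
    out["significant"] = (out["lo"] > 1.0) | (out["hi"] < 1.0)
    out.attrs["critical_value"] = crit
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# specialist classification
# ---------------------------------------------------------------------------

def classify_specialists(cell_means: pd.DataFrame, contrasts: pd.DataFrame) -> pd.Series:
    """Label each family from its standardized cell means and contrasts.

    Substrate specialist: both cells of one substrate above 1 and both of the
    other below, with every cross-substrate contrast significant; fire
    specialist: analogous across the fire factor; single-cell specialist: one
    cell above 1 and significantly above the other three; otherwise none.
    """
    missing = [c for c in CELLS if c not in cell_means.columns]
    if missing:
        raise InvalidDesignError(f"missing cell means: {missing}")

    sig = {}
    for _, r in contrasts.iterrows():
        a, b = r["contrast"].split(" / ")
        sig[(r["family"], a, b)] = bool(r["significant"])
        sig[(r["family"], b, a)] = bool(r["significant"])

    def _sig(f, pairs):
        return all(sig.get((f, a, b), False) for a, b in pairs)

    labels = {}
    for f, m in cell_means.iterrows():
        bl, ul, bs, us = (m[c] for c in CELLS)
        cross_sub = [("burnt-litter", "burnt-soil"), ("burnt-litter", "unburnt-soil"),
                     ("unburnt-litter", "burnt-soil"), ("unburnt-litter", "unburnt-soil")]
        cross_fire = [("burnt-litter", "unburnt-litter"), ("burnt-litter", "unburnt-soil"),
                      ("burnt-soil", "unburnt-litter"), ("burnt-soil", "unburnt-soil")]
        if bl > 1 and ul > 1 and bs < 1 and us < 1 and _sig(f, cross_sub):
            labels[f] = "litter"
        elif bs > 1 and us > 1 and bl < 1 and ul < 1 and _sig(f, cross_sub):
            labels[f] = "soil"
        elif bl > 1 and bs > 1 and ul < 1 and us < 1 and _sig(f, cross_fire):
            labels[f] = "fire"
        else:
            labels[f] = _single_or_none(f, m, _sig)
    return pd.Series(labels, name="specialist")


def _single_or_none(f, m, _sig) -> str:
    above = [c for c in CELLS if m[c] > 1]
    if len(above) == 1:
        c = above[0]
        others = [o for o in CELLS if o != c]
        if _sig(f, [(c, o) for o in others]):
            return c
    return "none"
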