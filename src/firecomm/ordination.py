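"""Hellinger transformation and partial constrained ordination (tb-RDA).

With Euclidean distances on Hellinger-transformed abundances, principal
coordinate analysis constrained by treatment variables is exactly redundancy
analysis of the transformed matrix, so the implementation works directly on
the (centered) Hellinger matrix:

1. variance explained by the *conditioning* variables (plot pairing, soil
   covariates) is removed by orthogonal projection;
2. the condition-residualized community matrix is projected onto the
   condition-residualized *constraint* (treatment) space; the eigenvectors of
   that fitted matrix are the constrained axes;
3. total variance splits exactly into conditional + constrained + residual
   fractions, with per-term marginal fractions and per-axis eigenvalues.

Marginal permutation tests follow the residualized-permutation scheme: rows
of the condition-residualized community matrix are freely permuted and the
marginal pseudo-F of the term (all other terms retained) is recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .errors import DegenerateSampleError, RankDeficiencyError

_SV_TOL = 1e-9


def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """Square root of row-relative abundances: rows get unit sum of squares."""
    X = np.asarray(table, dtype=float)
    if np.any(X < 0):
        raise ValueError("negative entries in abundance table")
    rs = X.sum(axis=1)
    if np.any(rs <= 0):
        idx = getattr(table, "index", pd.RangeIndex(len(X)))
        raise DegenerateSampleError(f"zero-sum rows: {list(np.asarray(idx)[rs <= 0])}")
    H = np.sqrt(X / rs[:, None])
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(H, index=table.index, columns=table.columns)
    return pd.DataFrame(H)


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def condition_matrix(
    metadata: pd.DataFrame, pair: bool = True, covariates: tuple = ()
) -> pd.DataFrame:
    """Conditioning variables: pair indicators plus standardized covariates."""
    parts = []
    if pair:
        parts.append(pd.get_dummies(metadata["pair"], prefix="pair", dtype=float))
    for cov in covariates:
        v = metadata[cov].astype(float)
        sd = v.std(ddof=0)
        parts.append(((v - v.mean()) / (sd if sd > 0 else 1.0)).to_frame(cov))
    if not parts:
        return pd.DataFrame(index=metadata.index)
    out = pd.concat(parts, axis=1)
    out.index = metadata.index
    return out


def treatment_terms(metadata: pd.DataFrame, include_pine: bool = False) -> dict:
    """Constraint term blocks: substrate, fire, their interaction (+ pine)."""
    sub = (metadata["substrate"] == "litter").astype(float).to_numpy()
    fire = (metadata["fire"] == "burnt").astype(float).to_numpy()
    terms = {
        "substrate": pd.DataFrame({"substrate_litter": sub}, index=metadata.index),
        "fire": pd.DataFrame({"fire_burnt": fire}, index=metadata.index),
        "substrate:fire": pd.DataFrame(
            {"substrate_litter:fire_burnt": sub * fire}, index=metadata.index
        ),
    }
    if include_pine:
        pine = (metadata["pine"] == "near").astype(float).to_numpy()
        terms["pine"] = pd.DataFrame({"pine_near": pine}, index=metadata.index)
    return terms


def _orth(X: np.ndarray) -> np.ndarray:
    """Orthonormal column basis (rank-revealing, tolerance on singular values)."""
    if X.size == 0 or X.shape[1] == 0:
        return np.zeros((X.shape[0], 0))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int((s > _SV_TOL * max(s[0], 1.0)).sum()) if s.size else 0
    return u[:, :r]


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# partial RDA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    fractions: dict
    site_scores: dict       # scaling name -> DataFrame (LC scores)
    site_scores_wa: dict    # scaling name -> DataFrame (weighted-average scores)
    taxon_scores: dict      # scaling name -> DataFrame
    axis_fractions: np.ndarray = field(default_factory=lambda: np.array([]))
    zero_variance: bool = False
    n_samples: int = 0
    rank_constrained: int = 0
    df_condition: int = 0


def _prepare(Y, condition, constraint):
    Yc = _center(np.asarray(Y, dtype=float))
    n = Yc.shape[0]
    if n < 2:
        raise ValueError("need more than one sample")
    C = np.asarray(condition, dtype=float) if condition is not None else np.zeros((n, 0))
    X = np.asarray(constraint, dtype=float)
    if C.shape[0] != n or X.shape[0] != n:
        raise ValueError("design rows do not match the community matrix")
    if C.shape[1] + X.shape[1] > n:
        comb = np.hstack([_center(C), _center(X)])
        if np.linalg.matrix_rank(comb) < comb.shape[1]:
            raise RankDeficiencyError(
                f"combined design has {comb.shape[1]} columns for {n} samples "
                "and is rank-deficient"
            )
    Qc = _orth(_center(C))
    Yr = Yc - Qc @ (Qc.T @ Yc)
    Xr = _center(X) - Qc @ (Qc.T @ _center(X))
    return Yc, Yr, Qc, Xr


def partial_rda(Y, constraint, condition=None) -> OrdinationResult:
    """Partial redundancy analysis of a (Hellinger) community matrix.

    ``constraint`` may be a matrix or a dict of term-name -> matrix blocks
    (per-term marginal fractions are reported for dicts). Fractions are of the
    total variance of the centered matrix and satisfy
    ``conditional + constrained + residual = 1``.
    """
    terms = None
    if isinstance(constraint, dict):
        terms = {k: np.asarray(v, dtype=float) for k, v in constraint.items()}
        Xfull = np.hstack(list(terms.values()))
    else:
        Xfull = np.asarray(constraint, dtype=float)

    Yc, Yr, Qc, Xr = _prepare(Y, condition, Xfull)
    n = Yc.shape[0]
    total_ss = float((Yc**2).sum())

    names = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    sites = list(Y.index) if isinstance(Y, pd.DataFrame) else None

    if total_ss <= _SV_TOL:
        empty = pd.DataFrame(index=sites)
        return OrdinationResult(
            eigenvalues=np.array([]),
            fractions={"conditional": 0.0, "constrained_total": 0.0, "residual": 0.0,
                       "by_term": {}},
            site_scores={"sites": empty, "taxa": empty},
            site_scores_wa={"sites": empty, "taxa": empty},
            taxon_scores={"sites": pd.DataFrame(index=names),
                          "taxa": pd.DataFrame(index=names)},
            zero_variance=True,
            n_samples=n,
        )

    ss_cond = float(((Qc @ (Qc.T @ Yc)) ** 2).sum())
    Qx = _orth(Xr)
    Fit = Qx @ (Qx.T @ Yr)
    ss_constr = float((Fit**2).sum())
    ss_resid = max(total_ss - ss_cond - ss_constr, 0.0)

    by_term = {}
    if terms is not None:
        for t in terms:
            Xred = np.hstack([v for k, v in terms.items() if k != t]) if len(terms) > 1 else np.zeros((n, 0))
            Xred_r = _center(Xred) - Qc @ (Qc.T @ _center(Xred))
            Qr = _orth(Xred_r)
            ss_red = float(((Qr @ (Qr.T @ Yr)) ** 2).sum())
            by_term[t] = (ss_constr - ss_red) / total_ss

    # constrained axes: SVD of the fitted matrix scaled to variance units
    u, s, vt = np.linalg.svd(Fit / np.sqrt(n - 1), full_matrices=False)
    r = int((s > _SV_TOL * max(s[0], 1.0)).sum()) if s.size else 0
    u, s, vt = u[:, :r], s[:r], vt[:r]
    eig = np.maximum(s**2, 0.0)  # non-increasing by SVD ordering

    # sign convention: first nonzero taxon loading of each axis positive
    V = vt.T
    for k in range(r):
        nz = np.flatnonzero(np.abs(V[:, k]) > _SV_TOL)
        if nz.size and V[nz[0], k] < 0:
            V[:, k] = -V[:, k]
            u[:, k] = -u[:, k]

    tot_var = total_ss / (n - 1)
    const = ((n - 1) * tot_var) ** 0.25
    lam_frac = np.sqrt(eig / tot_var)
    axes = [f"RDA{k + 1}" for k in range(r)]

    def _df(M, idx):
        return pd.DataFrame(M, index=idx, columns=axes)

    Ybar = Yr / np.sqrt(n - 1)
    wa_raw = Ybar @ V @ np.diag(1.0 / np.where(s > 0, s, 1.0))
    scores_sites_focus = {  # scaling 1: distances among sites preserved
        "site_lc": _df(u @ np.diag(lam_frac) * const, sites),
        "site_wa": _df(wa_raw @ np.diag(lam_frac) * const, sites),
        "taxa": _df(V * const, names),
    }
    scores_taxa_focus = {  # scaling 2: taxon correlations preserved
        "site_lc": _df(u * const, sites),
        "site_wa": _df(wa_raw * const, sites),
        "taxa": _df(V @ np.diag(lam_frac) * const, names),
    }

    fractions = {
        "conditional": ss_cond / total_ss,
        "constrained_total": ss_constr / total_ss,
        "residual": ss_resid / total_ss,
        "by_term": by_term,
    }
    return OrdinationResult(
        eigenvalues=eig,
        fractions=fractions,
        site_scores={"sites": scores_sites_focus["site_lc"], "taxa": scores_taxa_focus["site_lc"]},
        site_scores_wa={"sites": scores_sites_focus["site_wa"], "taxa": scores_taxa_focus["site_wa"]},
        taxon_scores={"sites": scores_sites_focus["taxa"], "taxa": scores_taxa_focus["taxa"]},
        axis_fractions=eig * (n - 1) / total_ss,
        zero_variance=False,
        n_samples=n,
        rank_constrained=r,
        df_condition=Qc.shape[1],
    )


def partition_percentages(conditional_pct: float, term_pcts: dict) -> dict:
    """Bookkeeping for a variance partition expressed in percent of total.

    Given the conditional percentage and per-term constrained percentages,
    returns the constrained total, the residual (everything sums to 100), and
    each term's share *of the constrained* variance.
    """
    constrained = float(sum(term_pcts.values()))
    residual = 100.0 - conditional_pct - constrained
    shares = {t: 100.0 * v / constrained for t, v in term_pcts.items()} if constrained else {}
    return {
        "constrained_total": constrained,
        "residual": residual,
        "term_share_of_constrained": shares,
    }


# ---------------------------------------------------------------------------
# marginal permutation test
# ---------------------------------------------------------------------------

def marginal_permutation_test(
    Y,
    constraint: dict,
    term: str,
    condition=None,
    n_perm: int = 999,
    seed: int = 0,
):
    """Marginal (all-other-terms-retained) pseudo-F permutation test.

    Returns ``(pseudo_F, (df_term, df_resid), p)``. The permutation stream is
    seeded; rows of the condition-residualized community matrix are permuted
    freely.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if term not in constraint:
        raise KeyError(f"term {term!r} not among constraint blocks {list(constraint)}")
    terms = {k: np.asarray(v, dtype=float) for k, v in constraint.items()}
    Xfull = np.hstack(list(terms.values()))
    Yc, Yr, Qc, Xr = _prepare(Y, condition, Xfull)
    n = Yc.shape[0]

    Qfull = _orth(Xr)
    Xred = (
        np.hstack([v for k, v in terms.items() if k != term])
        if len(terms) > 1
        else np.zeros((n, 0))
    )
    Xred_r = _center(Xred) - Qc @ (Qc.T @ _center(Xred))
    Qred = _orth(Xred_r)

    df_term = Qfull.shape[1] - Qred.shape[1]
    df_resid = n - 1 - Qc.shape[1] - Qfull.shape[1]
    if df_term < 1 or df_resid < 1:
        raise ValueError("no residual or term degrees of freedom")

    def _stats(Ymat):
        ss_full = float(((Qfull.T @ Ymat) ** 2).sum())
        ss_red = float(((Qred.T @ Ymat) ** 2).sum())
        ss_tot = float((Ymat**2).sum())
        ss_term = max(ss_full - ss_red, 0.0)
        # round-off can leave a tiny negative residual on separable data
        ss_res = max(ss_tot - ss_full, 0.0)
        if ss_res <= _SV_TOL * max(ss_tot, 1.0):
            return np.inf if ss_term > 0 else 0.0
        return (ss_term / df_term) / (ss_res / df_resid)

    f_obs = _stats(Yr)
    rng = stage_rng(seed, "permutation")
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _stats(Yr[perm]) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return f_obs, (df_term, df_resid), p


# ---------------------------------------------------------------------------
# taxonomic-level selection
# ---------------------------------------------------------------------------

def select_taxonomic_level(
    tables_by_rank: dict,
    constraint,
    condition=None,
    force: str | None = None,
):
    """Pick the rank whose ordination explains the most variance.

    Each table is Hellinger-transformed and run through :func:`partial_rda`;
    the winning rank maximizes conditional + constrained variance. Ties break
    toward the coarser rank (the order the dict lists them in, coarse first).
    Returns ``(rank, audit_table)``.
    """
    if force is not None:
        return force, pd.DataFrame(
            [{"rank": force, "explained": np.nan, "forced": True}]
        ).set_index("rank")
    if len(tables_by_rank) < 2:
        raise ValueError("need at least two ranks to compare (or use force=)")
    sample_sets = {k: tuple(v.index) for k, v in tables_by_rank.items()}
    if len(set(sample_sets.values())) != 1:
        raise ValueError(f"inconsistent sample sets across ranks: {list(sample_sets)}")
    rows = []
    for rank, tab in tables_by_rank.items():
        res = partial_rda(hellinger(tab), constraint, condition)
        explained = res.fractions["conditional"] + res.fractions["constrained_total"]
        rows.append({"rank": rank, "explained": explained, "forced": False})
    audit = pd.DataFrame(rows).set_index("rank")
    best = audit["explained"].round(12).idxmax()  # first (coarsest) wins ties
    return best, audit
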