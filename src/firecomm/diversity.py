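"""Family-level diversity metrics, multiplicative summaries, and beta-diversity
tests on the Hellinger matrix.

Richness S counts taxa with positive abundance; Shannon H uses natural logs;
evenness is Pielou's J = H / ln(S). Geometric-mean summaries report a
multiplicative standard-error factor f (a "times/divide" error bar), the
natural summary for ratio-scale quantities. PERMANOVA partitions Euclidean
sums of squares among/within groups with a seeded permutation p-value;
dispersion homogeneity is a one-way F on distances to own-group centroids
(the multivariate analogue of a variance-homogeneity test), also permuted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng
from .errors import DegenerateSampleError, InvalidDesignError
from .glmm import GLMMFit, fit_glmm_pql


def diversity_metrics(abundance_row) -> tuple[int, float, float]:
    """(richness S, Shannon H, Pielou J) for one sample's abundances."""
    x = np.asarray(abundance_row, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative abundances")
    pos = x[x > 0]
    if pos.size == 0:
        raise DegenerateSampleError("all-zero sample")
    p = pos / pos.sum()
    S = int(pos.size)
    H = float(-(p * np.log(p)).sum())
    J = float(H / np.log(S)) if S >= 2 else np.nan
    return S, H, J


def diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample S, H, J for a samples-by-taxa abundance table."""
    rows = [diversity_metrics(r) for _, r in table.iterrows()]
    return pd.DataFrame(rows, index=table.index, columns=["richness", "shannon", "evenness"])


@dataclass
class GmSummary:
    gm: float
    f: float      # multiplicative standard-error factor, >= 1
    n: int
    ci_lo: float
    ci_hi: float


def gm_summary(values, alpha: float = 0.05) -> GmSummary:
    """Geometric mean with multiplicative SE factor and t-based CI."""
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric-mean summary needs strictly positive values")
    lx = np.log(x)
    n = x.size
    gm = float(np.exp(lx.mean()))
    se = float(lx.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    f = float(np.exp(se))
    tq = float(stats.t.ppf(1 - alpha / 2, n - 1)) if n > 1 else 0.0
    return GmSummary(gm, f, n, gm / f**tq if n > 1 else gm, gm * f**tq if n > 1 else gm)


# ---------------------------------------------------------------------------
# diversity GLMMs
# ---------------------------------------------------------------------------

def fit_richness_glmm(S, metadata: pd.DataFrame, **kw) -> GLMMFit:
    """Poisson log-link GLMM of richness with pair random intercepts."""
    S = np.asarray(S)
    if not np.all(S == np.asarray(S, dtype=int)) or np.any(S <= 0):
        raise ValueError("richness must be positive integers")
    return fit_glmm_pql(S.astype(float), metadata, family="poisson", **kw)


def compress_unit_interval(J, n: int | None = None) -> tuple[np.ndarray, bool]:
    """Standard (J*(n-1)+0.5)/n squeeze applied only when values touch 0/1."""
    J = np.asarray(J, dtype=float)
    n = J.size if n is None else n
    if np.any((J < 0) | (J > 1)):
        raise ValueError("evenness outside [0, 1]")
    if np.any((J == 0) | (J == 1)):
        return (J * (n - 1) + 0.5) / n, True
    return J, False


def fit_evenness_glmm(J, metadata: pd.DataFrame, **kw) -> GLMMFit:
    """Beta logit-link GLMM of evenness with pair random intercepts."""
    Jc, squeezed = compress_unit_interval(J)
    fit = fit_glmm_pql(Jc, metadata, family="beta", **kw)
    if squeezed:
        fit.notes.append("boundary evenness values compressed to (0,1)")
    return fit


# ---------------------------------------------------------------------------
# PERMANOVA and dispersion
# ---------------------------------------------------------------------------

def _check_groups(Y, groups):
    Y = np.asarray(Y, dtype=float)
    g = np.asarray(groups)
    if g.shape[0] != Y.shape[0]:
        raise InvalidDesignError("groups do not align with rows")
    labels, counts = np.unique(g, return_counts=True)
    if labels.size < 2:
        raise InvalidDesignError("need at least two groups")
    if counts.min() < 2:
        bad = labels[counts < 2].tolist()
        raise InvalidDesignError(f"singleton group(s): {bad}")
    return Y, g, labels


def _ss_partition(Y, g, labels):
    tot = float(((Y - Y.mean(axis=0)) ** 2).sum())
    within = 0.0
    for lab in labels:
        sub = Y[g == lab]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return tot - within, within


def permanova(Y, groups, n_perm: int = 999, seed: int = 0):
    """Euclidean PERMANOVA pseudo-F with seeded permutation p-value.

    Returns ``(pseudo_F, (df_among, df_within), p)``. Groups may encode a main
    effect (two labels) or the full substrate-by-fire interaction (four).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y, g, labels = _check_groups(Y, groups)
    n, a = Y.shape[0], labels.size
    df1, df2 = a - 1, n - a
    among, within = _ss_partition(Y, g, labels)
    f_obs = (among / df1) / (within / df2)
    rng = stage_rng(seed, "permutation")
    exceed = 0
    for _ in range(n_perm):
        gp = g[rng.permutation(n)]
        am, wi = _ss_partition(Y, gp, labels)
        if (am / df1) / (wi / df2) >= f_obs:
            exceed += 1
    return f_obs, (df1, df2), (1 + exceed) / (1 + n_perm)


def group_centroid_distances(Y, groups) -> np.ndarray:
    """Euclidean distance of each sample to its own group centroid."""
    Y, g, labels = _check_groups(Y, groups)
    d = np.empty(Y.shape[0])
    for lab in labels:
        m = g == lab
        d[m] = np.linalg.norm(Y[m] - Y[m].mean(axis=0), axis=1)
    return d


def dispersion_homogeneity(Y, groups, n_perm: int = 999, seed: int = 0):
    """Multivariate dispersion test: one-way F on distances to group centroids.

    The permutation shuffles group labels and recomputes centroids and
    distances each time, so the permuted statistics are exchangeable with the
    observed one and the null p-value is uniform even for small groups.
    Returns ``(F, (df1, df2), p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y, g, labels = _check_groups(Y, groups)
    n, a = Y.shape[0], labels.size
    df1, df2 = a - 1, n - a

    def _f(gv):
        d = np.empty(n)
        for lab in labels:
            m = gv == lab
            d[m] = np.linalg.norm(Y[m] - Y[m].mean(axis=0), axis=1)
        grand = d.mean()
        among = sum((gv == lab).sum() * (d[gv == lab].mean() - grand) ** 2 for lab in labels)
        within = sum(((d[gv == lab] - d[gv == lab].mean()) ** 2).sum() for lab in labels)
        if within == 0.0:
            return 0.0 if among == 0.0 else np.inf
        return (among / df1) / (within / df2)

    f_obs = _f(g)
    rng = stage_rng(seed, "permutation")
    exceed = 0
    for _ in range(n_perm):
        if _f(g[rng.permutation(n)]) >= f_obs:
            exceed += 1
    return f_obs, (df1, df2), (1 + exceed) / (1 + n_perm)
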