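"""Within-sample geometric-mean scaling and group-wise overdispersion taming.

``geometric_mean_scale`` divides every count in a sample by the geometric mean
of that sample's *positive* counts, so a value of 1 marks a taxon sitting at
the sample's typical abundance and zeros stay exactly zero.

``group_variance_standardize`` pulls extreme counts toward their group mean:
within each group (the four substrate-by-fire cells) a per-taxon negative
binomial mean/dispersion is fitted by method of moments leave-one-out, and any
count whose Pearson residual exceeds the cap is shrunk to the value sitting
exactly at the cap. Counts are never increased and zeros are never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, InvalidDesignError


def geometric_mean_scale(count_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample by the geometric mean of its positive counts.

    Returns ``(scaled_table, scale_factors)``. Raises on an all-zero sample.
    """
    X = count_table.to_numpy(dtype=float)
    pos = X > 0
    empty = ~pos.any(axis=1)
    if empty.any():
        bad = list(count_table.index[empty])
        raise DegenerateSampleError(f"sample(s) with no positive counts: {bad}")
    with np.errstate(divide="ignore"):
        logs = np.where(pos, np.log(np.where(pos, X, 1.0)), 0.0)
    gm = np.exp(logs.sum(axis=1) / pos.sum(axis=1))
    out = pd.DataFrame(X / gm[:, None], index=count_table.index, columns=count_table.columns)
    factors = pd.Series(gm, index=count_table.index, name="scale_factor")
    return out, factors


def group_variance_standardize(
    count_table: pd.DataFrame,
    groups: pd.Series,
    cap: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shrink within-group outliers to a Pearson-residual cap.

    ``groups`` maps each sample (row) to its group label. For each taxon and
    group the NB mean/variance is estimated from the *other* group members
    (leave-one-out, so a lone outlier cannot mask itself); an observation with
    ``(x - m) / sd > cap`` is replaced by ``round(m + cap * sd)``, where ``sd``
    is the fitted NB standard deviation floored at the Poisson value
    ``sqrt(m)``. Returns the adjusted table and a log of shrink events.
    """
    groups = pd.Series(groups).reindex(count_table.index)
    if groups.isna().any():
        raise InvalidDesignError("groups do not cover every sample")
    X = count_table.to_numpy(dtype=float)
    adj = X.copy()
    events = []
    for g, idx in groups.groupby(groups).groups.items():
        rows = count_table.index.get_indexer(idx)
        n = rows.size
        if n < 3:
            raise InvalidDesignError(f"group {g!r} has {n} samples; need >= 3")
        sub = X[rows]  # (n, taxa)
        tot = sub.sum(axis=0)
        totsq = (sub**2).sum(axis=0)
        # leave-one-out mean and variance per observation
        m = (tot[None, :] - sub) / (n - 1)
        var = (totsq[None, :] - sub**2 - (n - 1) * m**2) / (n - 2)
        var = np.maximum(var, 0.0)
        # NB regime only: a taxon whose within-group variance <= mean is never touched
        gate = sub.var(axis=0, ddof=1) > sub.mean(axis=0)
        sd = np.sqrt(np.maximum(var, m))  # Poisson floor
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = np.where(sd > 0, (sub - m) / sd, 0.0)
        hit = (resid > cap) & gate[None, :] & (sub > m)
        if hit.any():
            shrunk = np.round(m + cap * sd)
            for i, j in zip(*np.nonzero(hit)):
                events.append(
                    {
                        "sample_id": count_table.index[rows[i]],
                        "taxon": count_table.columns[j],
                        "group": g,
                        "old": sub[i, j],
                        "new": shrunk[i, j],
                    }
                )
            sub = np.where(hit, shrunk, sub)
            adj[rows] = sub
    log = pd.DataFrame(events, columns=["sample_id", "taxon", "group", "old", "new"])
    out = pd.DataFrame(adj, index=count_table.index, columns=count_table.columns)
    if all(np.issubdtype(t, np.integer) for t in count_table.dtypes):
        out = out.astype(np.int64)
    return out, log
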