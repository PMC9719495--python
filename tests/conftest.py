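import numpy as np
import pandas as pd
import pytest

from firecomm import simulate as sim


@pytest.fixture(scope="session")
def design120():
    """The full study layout: 30 pairs, 60 plots, 120 samples."""
    return sim.generate_design(30, 0.5, seed=1)


@pytest.fixture(scope="session")
def small_design():
    return sim.generate_design(6, 0.5, seed=0)


@pytest.fixture(scope="session")
def study_spec():
    return sim.EffectSpec.study_default()


@pytest.fixture(scope="session")
def study_data(design120, study_spec):
    """One full synthetic dataset (counts, taxonomy, truth) under the defaults."""
    counts, taxmap, truth = sim.generate_counts(design120, study_spec, seed=1)
    return counts, taxmap, truth


@pytest.fixture(scope="session")
def family_table(study_data):
    counts, _, truth = study_data
    fam = counts.T.groupby(truth["esv_family"].reindex(counts.columns).to_numpy()).sum().T
    return fam


def rda_oracle(Y, X, C=None):
    """Independent partial-RDA oracle: explicit hat matrices + eigh.

    Deliberately different route from the package implementation (which uses
    orthonormal bases + SVD of the fitted matrix).
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    total = (Yc**2).sum()

    def hat(M):
        M = np.asarray(M, dtype=float)
        if M.size == 0 or M.shape[1] == 0:
            return np.zeros((n, n))
        Mc = M - M.mean(axis=0)
        return Mc @ np.linalg.pinv(Mc.T @ Mc) @ Mc.T

    Hc = hat(C) if C is not None else np.zeros((n, n))
    Yr = Yc - Hc @ Yc
    Xc = np.asarray(X, dtype=float) - np.asarray(X, dtype=float).mean(axis=0)
    Xr = Xc - Hc @ Xc
    Hx = np.zeros((n, n)) if Xr.shape[1] == 0 else Xr @ np.linalg.pinv(Xr.T @ Xr) @ Xr.T
    Fit = Hx @ Yr
    ss_cond = ((Hc @ Yc) ** 2).sum()
    ss_constr = (Fit**2).sum()
    lam, _ = np.linalg.eigh(Fit.T @ Fit / (n - 1))
    lam = np.sort(lam)[::-1]
    lam = lam[lam > 1e-12]
    return {
        "conditional": ss_cond / total,
        "constrained": ss_constr / total,
        "residual": (total - ss_cond - ss_constr) / total,
        "eigenvalues": lam,
    }
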