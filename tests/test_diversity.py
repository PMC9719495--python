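import numpy as np
import pandas as pd
import pytest

from firecomm import diversity as dv
from firecomm.errors import DegenerateFitError, DegenerateSampleError, InvalidDesignError


class TestMetrics:
    def test_richness_counts_positive_entries(self):
        S, _, _ = dv.diversity_metrics([0, 2, 5, 0])
        assert S == 2

    def test_uniform_community_maximally_even(self):
        S, H, J = dv.diversity_metrics([3, 3, 3, 3])
        assert S == 4
        assert H == pytest.approx(np.log(4))
        assert J == pytest.approx(1.0)

    def test_formula_oracle_values(self):
        _, H, J = dv.diversity_metrics([0.5, 0.25, 0.25])
        assert H == pytest.approx(1.03972, abs=1e-5)
        assert J == pytest.approx(0.94639, abs=1e-5)

    def test_singleton_sample(self):
        S, H, J = dv.diversity_metrics([0, 7, 0])
        assert S == 1 and H == 0.0 and np.isnan(J)

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateSampleError):
            dv.diversity_metrics([0, 0, 0])

    @pytest.mark.parametrize("k", [0.2, 1.0, 50.0])
    def test_evenness_scale_invariant(self, k):
        x = np.array([1, 4, 2, 9], dtype=float)
        assert dv.diversity_metrics(x)[2] == pytest.approx(dv.diversity_metrics(x * k)[2])


class TestGmSummary:
    def test_constant_values(self):
        g = dv.gm_summary([5, 5, 5])
        assert g.gm == pytest.approx(5.0) and g.f == pytest.approx(1.0)

    def test_two_values(self):
        assert dv.gm_summary([4, 9]).gm == pytest.approx(6.0)

    def test_log_scale_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1.0, 0.4, 50)
        g = dv.gm_summary(x)
        lx = np.log(x)
        assert g.gm == pytest.approx(np.exp(lx.mean()), abs=1e-10)
        assert np.log(g.f) == pytest.approx(lx.std(ddof=1) / np.sqrt(50), abs=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            dv.gm_summary([1.0, 0.0])


class TestDiversityGLMMs:
    def test_constant_richness_all_effects_zero(self, design120):
        fit = dv.fit_richness_glmm(np.full(len(design120), 66), design120)
        assert (fit.tests["chi2"] == 0).all()
        assert (fit.tests["p"] == 1.0).all()

    def test_richness_rate_ratio_recovered(self):
        from firecomm import simulate as sim

        rng = np.random.default_rng(0)
        ests = []
        for rep in range(10):
            d = sim.generate_design(100, 0.5, seed=rep)
            lam = np.where(d["substrate"] == "litter", 60 * 1.5, 60)
            S = rng.poisson(lam) + 1
            fit = dv.fit_richness_glmm(S, d)
            # sum-coded substrate main effect: log-ratio = 2 * coefficient
            coef = fit.params[[c for c in fit.params.index if "substrate" in c][0]]
            ests.append(np.exp(2 * abs(coef)))
        assert 1.35 <= np.median(ests) <= 1.65

    def test_unpaired_design_rejected(self, design120):
        meta = design120.copy()
        meta["pair"] = np.arange(len(meta)).astype(str)
        with pytest.raises(InvalidDesignError):
            dv.fit_richness_glmm(np.full(len(meta), 5), meta)

    def test_evenness_shift_recovered(self):
        from scipy.special import expit
        from firecomm import simulate as sim

        rng = np.random.default_rng(1)
        ests = []
        for rep in range(10):
            d = sim.generate_design(100, 0.5, seed=rep)
            eta = 1.0 + np.where(d["substrate"] == "litter", 0.5, 0.0)
            mu = expit(eta)
            phi = 60
            J = rng.beta(mu * phi, (1 - mu) * phi)
            fit = dv.fit_evenness_glmm(J, d)
            coef = fit.params[[c for c in fit.params.index if "substrate" in c][0]]
            ests.append(2 * abs(coef))
        assert abs(np.median(ests) - 0.5) <= 0.15

    def test_constant_evenness_rejected(self, design120):
        with pytest.raises(DegenerateFitError):
            dv.fit_evenness_glmm(np.full(len(design120), 0.8), design120)

    def test_out_of_range_evenness_rejected(self, design120):
        J = np.full(len(design120), 0.5)
        J[0] = 1.2
        with pytest.raises(ValueError):
            dv.fit_evenness_glmm(J, design120)


class TestPermanova:
    def test_separated_clouds_minimal_p(self):
        rng = np.random.default_rng(0)
        Y = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (10, 3))])
        g = np.repeat(["a", "b"], 10)
        f, (df1, df2), p = dv.permanova(Y, g, n_perm=999, seed=0)
        assert (df1, df2) == (1, 18)
        assert p == pytest.approx(1 / 1000)
        assert f > 100

    def test_f_matches_ss_oracle_and_skbio(self):
        rng = np.random.default_rng(1)
        Y = rng.random((10, 4))
        g = np.array(list("aabbbaabbb"))
        f, _, _ = dv.permanova(Y, g, n_perm=9, seed=0)
        # oracle 1: direct SS partition
        tot = ((Y - Y.mean(axis=0)) ** 2).sum()
        within = sum(((Y[g == lab] - Y[g == lab].mean(axis=0)) ** 2).sum() for lab in "ab")
        f_exp = ((tot - within) / 1) / (within / 8)
        assert f == pytest.approx(f_exp, abs=1e-10)
        # oracle 2: scikit-bio on the Euclidean distance matrix
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform

        dm = skbio.DistanceMatrix(squareform(pdist(Y)), ids=[str(i) for i in range(10)])
        res = skbio.stats.distance.permanova(dm, list(g), permutations=9)
        assert f == pytest.approx(res["test statistic"], abs=1e-8)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        Y = rng.random((12, 3))
        g = np.repeat(["a", "b"], 6)
        f1, _, _ = dv.permanova(Y, g, n_perm=9, seed=0)
        f2, _, _ = dv.permanova(Y, np.where(g == "a", "b", "a"), n_perm=9, seed=0)
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_reproducible_p(self):
        rng = np.random.default_rng(3)
        Y = rng.random((16, 3))
        g = np.repeat(["a", "b"], 8)
        r1 = dv.permanova(Y, g, n_perm=199, seed=5)
        r2 = dv.permanova(Y, g, n_perm=199, seed=5)
        assert r1 == r2

    def test_singleton_group_rejected(self):
        with pytest.raises(InvalidDesignError):
            dv.permanova(np.random.default_rng(0).random((5, 2)), ["a", "a", "a", "a", "b"])


class TestDispersion:
    def test_translated_groups_have_zero_f(self):
        rng = np.random.default_rng(0)
        A = rng.random((8, 3))
        Y = np.vstack([A, A + 100.0])
        g = np.repeat(["a", "b"], 8)
        f, _, _ = dv.dispersion_homogeneity(Y, g, n_perm=99, seed=0)
        assert f == pytest.approx(0.0, abs=1e-18)

    def test_scaled_group_detected(self):
        rng = np.random.default_rng(1)
        A = rng.random((12, 3))
        B = (A - A.mean(axis=0)) * 10 + A.mean(axis=0)
        Y = np.vstack([A, B])
        g = np.repeat(["a", "b"], 12)
        _, _, p = dv.dispersion_homogeneity(Y, g, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_distances_match_arithmetic_oracle(self):
        rng = np.random.default_rng(2)
        Y = rng.random((9, 4))
        g = np.array(list("aaabbbccc"))
        d = dv.group_centroid_distances(Y, g)
        for lab in "abc":
            sub = Y[g == lab]
            exp = np.linalg.norm(sub - sub.mean(axis=0), axis=1)
            assert d[g == lab] == pytest.approx(exp, abs=1e-12)
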