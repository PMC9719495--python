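import numpy as np
import pandas as pd
import pytest

from conftest import rda_oracle
from firecomm import ordination as ordn
from firecomm.errors import DegenerateSampleError, RankDeficiencyError


class TestHellinger:
    def test_known_row(self):
        out = ordn.hellinger(pd.DataFrame([[1, 1, 2]]))
        assert out.iloc[0].tolist() == pytest.approx([0.5, 0.5, 0.70711], abs=1e-5)

    @pytest.mark.parametrize("k", [1, 3.5, 1000])
    def test_scale_invariance_single_taxon(self, k):
        out = ordn.hellinger(pd.DataFrame([[k, 0, 0]]))
        assert out.iloc[0].tolist() == pytest.approx([1.0, 0.0, 0.0])

    def test_rows_have_unit_squared_sum(self):
        rng = np.random.default_rng(0)
        out = ordn.hellinger(pd.DataFrame(rng.random((10, 7)) + 0.01))
        assert (out.to_numpy() ** 2).sum(axis=1) == pytest.approx(np.ones(10), abs=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(DegenerateSampleError):
            ordn.hellinger(pd.DataFrame([[1, 2], [0, 0]]))


def _random_instance(seed, n=12, m=5):
    rng = np.random.default_rng(seed)
    Y = pd.DataFrame(rng.random((n, m)))
    C = rng.standard_normal((n, 1))
    X = np.zeros((n, 2))
    X[rng.permutation(n)[: n // 2], 0] = 1.0
    X[:, 1] = rng.standard_normal(n)
    return Y, X, C


class TestPartialRDA:
    def test_perfect_group_separation_fully_constrained(self):
        groups = np.repeat([0, 1, 2], 4)
        Y = pd.DataFrame(np.column_stack([groups == g for g in range(3)]).astype(float))
        X = pd.get_dummies(groups).to_numpy(float)
        res = ordn.partial_rda(Y, X)
        assert res.fractions["constrained_total"] == pytest.approx(1.0, abs=1e-9)
        assert res.fractions["residual"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_columns_flagged_zero_variance(self):
        Y = pd.DataFrame(np.ones((8, 3)))
        X = np.arange(8.0).reshape(-1, 1)
        res = ordn.partial_rda(Y, X)
        assert res.zero_variance
        assert res.fractions["constrained_total"] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_projection_oracle(self, seed):
        Y, X, C = _random_instance(seed)
        res = ordn.partial_rda(Y, X, C)
        exp = rda_oracle(Y, X, C)
        assert res.fractions["conditional"] == pytest.approx(exp["conditional"], abs=1e-8)
        assert res.fractions["constrained_total"] == pytest.approx(exp["constrained"], abs=1e-8)
        assert res.fractions["residual"] == pytest.approx(exp["residual"], abs=1e-8)
        assert res.eigenvalues == pytest.approx(exp["eigenvalues"], abs=1e-8)

    def test_fraction_conservation(self):
        for seed in range(5):
            Y, X, C = _random_instance(seed, n=15, m=8)
            fr = ordn.partial_rda(Y, X, C).fractions
            total = fr["conditional"] + fr["constrained_total"] + fr["residual"]
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalues_nonincreasing_nonnegative(self):
        Y, X, C = _random_instance(3, n=20, m=10)
        eig = ordn.partial_rda(Y, X, C).eigenvalues
        assert np.all(np.diff(eig) <= 1e-12)
        assert np.all(eig >= -1e-12)

    def test_rank_deficient_overwide_design_rejected(self):
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(rng.random((6, 3)))
        X = np.ones((6, 4))  # collinear and combined cols > n with condition
        C = np.ones((6, 3))
        with pytest.raises(RankDeficiencyError):
            ordn.partial_rda(Y, X, C)

    def test_unconstrained_pcoa_equals_pca_of_hellinger(self):
        """Euclidean PCoA on Hellinger data = PCA of the Hellinger matrix."""
        rng = np.random.default_rng(5)
        H = ordn.hellinger(pd.DataFrame(rng.random((14, 6)) + 0.01)).to_numpy()
        n = H.shape[0]
        # classical PCoA: double-centred squared Euclidean distances
        D2 = ((H[:, None, :] - H[None, :, :]) ** 2).sum(axis=2)
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ D2 @ J
        pcoa_eig = np.sort(np.linalg.eigvalsh(G))[::-1] / (n - 1)
        Hc = H - H.mean(axis=0)
        pca_eig = np.sort(np.linalg.eigvalsh(Hc.T @ Hc))[::-1] / (n - 1)
        k = min(len(pca_eig), len(pcoa_eig))
        assert pcoa_eig[:k] == pytest.approx(pca_eig[:k], abs=1e-8)


class TestMarginalTest:
    def _fixed_instance(self):
        rng = np.random.default_rng(42)
        Y = pd.DataFrame(rng.random((8, 3)))
        terms = {
            "a": np.repeat([0.0, 1.0], 4).reshape(-1, 1),
            "b": rng.standard_normal((8, 1)),
        }
        return Y, terms

    def test_f_matches_ss_partition_oracle(self):
        Y, terms = self._fixed_instance()
        f, (df1, df2), _ = ordn.marginal_permutation_test(Y, terms, "a", n_perm=9, seed=0)
        # independent recomputation via explicit hat matrices
        full = rda_oracle(Y, np.hstack([terms["a"], terms["b"]]))
        red = rda_oracle(Y, terms["b"])
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        tot = (Yc**2).sum()
        ss_term = (full["constrained"] - red["constrained"]) * tot
        ss_res = full["residual"] * tot
        f_exp = (ss_term / df1) / (ss_res / df2)
        assert f == pytest.approx(f_exp, abs=1e-10)

    def test_minimal_p_on_separable_term(self):
        groups = np.repeat([0.0, 1.0], 12)
        Y = pd.DataFrame(np.column_stack([groups, 1 - groups]))
        terms = {"g": groups.reshape(-1, 1)}
        _, _, p = ordn.marginal_permutation_test(Y, terms, "g", n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_seeded_reproducibility(self):
        Y, terms = self._fixed_instance()
        r1 = ordn.marginal_permutation_test(Y, terms, "a", n_perm=99, seed=7)
        r2 = ordn.marginal_permutation_test(Y, terms, "a", n_perm=99, seed=7)
        assert r1 == r2

    def test_bad_nperm_rejected(self):
        Y, terms = self._fixed_instance()
        with pytest.raises(ValueError):
            ordn.marginal_permutation_test(Y, terms, "a", n_perm=0, seed=0)


class TestLevelSelection:
    def test_noise_columns_dilute_explained_fraction(self):
        rng = np.random.default_rng(1)
        groups = np.repeat([0.0, 1.0], 6)
        signal = pd.DataFrame(
            np.column_stack([groups * 10 + rng.random(12), rng.random(12)]),
            columns=["t1", "t2"],
        )
        noisy = signal.copy()
        for j in range(6):
            noisy[f"noise{j}"] = rng.random(12) * 10
        terms = {"g": groups.reshape(-1, 1)}
        best, audit = ordn.select_taxonomic_level(
            {"clean": signal + 0.01, "noisy": noisy + 0.01}, terms
        )
        assert best == "clean"
        assert audit.loc["clean", "explained"] > audit.loc["noisy", "explained"]

    def test_family_beats_genus_on_planted_family_effects(self):
        """The rank carrying the planted effects wins against the finer rank
        that splits (and so dilutes) them, in >= 18 of 20 seeds."""
        from firecomm import simulate as sim
        from firecomm import taxonomy as tax

        wins = 0
        for seed in range(20):
            d = sim.generate_design(30, 0.5, seed=seed)
            spec = sim.EffectSpec.study_default()
            counts, taxmap, _ = sim.generate_counts(d, spec, seed=seed)
            tables = {
                rank: tax.aggregate_by_rank(counts, taxmap, rank)[0]
                for rank in ("family", "genus")
            }
            best, _ = ordn.select_taxonomic_level(
                tables, ordn.treatment_terms(d), ordn.condition_matrix(d)
            )
            wins += best == "family"
        assert wins >= 18

    def test_single_rank_requires_force(self):
        Y = pd.DataFrame(np.random.default_rng(0).random((8, 3)))
        with pytest.raises(ValueError):
            ordn.select_taxonomic_level({"family": Y}, {"g": np.ones((8, 1))})
        best, audit = ordn.select_taxonomic_level(
            {"family": Y}, {"g": np.ones((8, 1))}, force="family"
        )
        assert best == "family" and audit.loc["family", "forced"]

    def test_mismatched_sample_sets_rejected(self):
        a = pd.DataFrame(np.ones((4, 2)), index=list("abcd"))
        b = pd.DataFrame(np.ones((4, 2)), index=list("abce"))
        with pytest.raises(ValueError):
            ordn.select_taxonomic_level({"x": a, "y": b}, {"g": np.ones((4, 1))})


def test_partition_percentage_bookkeeping():
    out = ordn.partition_percentages(20.0, {"substrate": 60.0, "fire+interaction": 7.5})
    assert out["constrained_total"] == pytest.approx(67.5)
    assert out["residual"] == pytest.approx(12.5)
    assert out["term_share_of_constrained"]["substrate"] == pytest.approx(88.9, abs=0.05)
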