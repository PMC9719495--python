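import numpy as np
import pandas as pd
import pytest

from firecomm import influential as infl
from firecomm import ordination as ordn
from firecomm import simulate as sim
from firecomm.errors import DegenerateFitError, InvalidDesignError


class TestThreshold:
    def test_unit_cross_centroids(self):
        cent = pd.DataFrame([[1, 0], [0, 1], [-1, 0], [0, -1]])
        assert infl.influential_threshold(cent) == pytest.approx(1.0)

    def test_three_four_five(self):
        assert infl.influential_threshold(pd.DataFrame([[3, 4]])) == pytest.approx(5.0)

    def test_diagonal_centroids(self):
        cent = pd.DataFrame([[1, 1], [1, -1], [-1, 1], [-1, -1]])
        assert infl.influential_threshold(cent) == pytest.approx(np.sqrt(2), abs=1e-5)


class TestCentroids:
    def _result(self, scores, index):
        class R:
            site_scores = {"taxa": pd.DataFrame(scores, index=index, columns=["RDA1", "RDA2"])}
        return R()

    def _meta(self, cells, index):
        return pd.DataFrame(
            {
                "sample_id": index,
                "fire": [c.split("-")[0] for c in cells],
                "substrate": [c.split("-")[1] for c in cells],
            }
        )

    def test_centroids_are_cell_means(self):
        rng = np.random.default_rng(0)
        cells = [c for c in sim.CELLS for _ in range(4)]
        idx = [f"s{i}" for i in range(16)]
        scores = rng.standard_normal((16, 2))
        cent = infl.interaction_centroids(self._result(scores, idx), self._meta(cells, idx))
        for k, cell in enumerate(sim.CELLS):
            assert cent.loc[cell].to_numpy() == pytest.approx(
                scores[4 * k : 4 * k + 4].mean(axis=0), abs=1e-12
            )

    def test_identical_scores_identical_centroids(self):
        cells = list(sim.CELLS) * 2
        idx = [f"s{i}" for i in range(8)]
        cent = infl.interaction_centroids(
            self._result(np.ones((8, 2)), idx), self._meta(cells, idx)
        )
        assert np.allclose(cent.to_numpy(), 1.0)

    def test_empty_cell_rejected(self):
        cells = ["burnt-litter"] * 8
        idx = [f"s{i}" for i in range(8)]
        with pytest.raises(InvalidDesignError):
            infl.interaction_centroids(
                self._result(np.ones((8, 2)), idx), self._meta(cells, idx)
            )


class TestSelection:
    def test_threshold_rule(self):
        scores = pd.DataFrame([[2, 0], [0.5, 0.5]], index=["far", "near"])
        sel, dist = infl.select_influential(scores, np.sqrt(2))
        assert sel == ["far"]
        assert dist["near"] == pytest.approx(np.sqrt(0.5))

    def test_all_at_origin_selects_nothing(self):
        scores = pd.DataFrame(np.zeros((5, 2)))
        sel, _ = infl.select_influential(scores, 0.1)
        assert sel == []

    @pytest.mark.parametrize("k", [0.1, 1.0, 17.0])
    def test_scale_consistency(self, k):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.standard_normal((10, 2)))
        cent = pd.DataFrame(rng.standard_normal((4, 2)))
        base, _ = infl.select_influential(scores, infl.influential_threshold(cent))
        scaled, _ = infl.select_influential(scores * k, infl.influential_threshold(cent * k))
        assert base == scaled

    def test_per_axis_variant(self):
        scores = pd.DataFrame([[0.9, 0.9]], index=["f"])
        sel_d, _ = infl.select_influential(scores, 1.0, mode="distance")
        sel_a, _ = infl.select_influential(scores, 1.0, mode="per_axis")
        assert sel_d == ["f"] and sel_a == []


def tweedie_rvs(mu, p, phi, rng):
    """Compound Poisson-Gamma sampler (independent of the GLM route)."""
    mu = np.asarray(mu, dtype=float)
    lam = mu ** (2 - p) / (phi * (2 - p))
    alpha = (2 - p) / (p - 1)
    scale = phi * (p - 1) * mu ** (p - 1)
    N = rng.poisson(lam)
    out = np.zeros_like(mu)
    pos = N > 0
    out[pos] = rng.gamma(N[pos] * alpha, np.broadcast_to(scale, mu.shape)[pos])
    return out


class TestTweedieFit:
    def test_standardized_values_average_one(self, design120):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            rng.gamma(2, 1, size=(len(design120), 3)),
            index=design120["sample_id"],
            columns=["A", "B", "C"],
        )
        std, excluded = infl.within_family_standardize(tab, ["A", "B", "C"])
        assert excluded == []
        assert std.mean(axis=0).to_numpy() == pytest.approx(np.ones(3), abs=1e-12)

    def test_power_profile_recovers_simulation_power(self):
        rng = np.random.default_rng(1)
        d = sim.generate_design(40, 0.5, seed=0)
        y = tweedie_rvs(np.full(len(d), 2.0), 1.5, 1.0, rng)
        tab = pd.DataFrame({"FamA": y}, index=d["sample_id"])
        fit = infl.fit_tweedie_interaction(tab, d, ["FamA"])
        assert 1.3 <= fit.power <= 1.7
        assert (fit.cell_means.to_numpy() > 0).all()

    def test_family_absent_from_cell_excluded_with_warning(self, small_design):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame(
            rng.gamma(2, 1, size=(len(small_design), 2)),
            index=small_design["sample_id"],
            columns=["A", "B"],
        )
        litter_burnt = (small_design["substrate"] == "litter") & (small_design["fire"] == "burnt")
        tab.loc[litter_burnt.to_numpy(), "B"] = 0.0
        with pytest.warns(UserWarning, match="B"):
            fit = infl.fit_tweedie_interaction(tab, small_design, ["A", "B"])
        assert fit.families == ["A"] and "B" in fit.excluded

    def test_zero_variance_rejected(self, small_design):
        tab = pd.DataFrame(
            np.ones((len(small_design), 1)), index=small_design["sample_id"], columns=["A"]
        )
        with pytest.raises(DegenerateFitError):
            infl.fit_tweedie_interaction(tab, small_design, ["A"])


@pytest.fixture(scope="module")
def strong_fit():
    rng = np.random.default_rng(3)
    d = sim.generate_design(30, 0.5, seed=0)
    litter = (d["substrate"] == "litter").to_numpy()
    mu_lit = np.where(litter, 3.0, 0.3)
    burnt = (d["fire"] == "burnt").to_numpy()
    mu_fire = np.where(burnt, 3.0, 0.3)
    tab = pd.DataFrame(
        {
            "LitterFam": tweedie_rvs(mu_lit, 1.5, 0.3, rng),
            "FireFam": tweedie_rvs(mu_fire, 1.5, 0.3, rng),
            "NullFam": tweedie_rvs(np.full(len(d), 1.0), 1.5, 0.3, rng),
        },
        index=d["sample_id"],
    )
    fit = infl.fit_tweedie_interaction(tab, d, list(tab.columns))
    contrasts = infl.treatment_contrasts(fit, seed=0)
    return fit, contrasts


class TestContrastsAndClassification:
    def test_simultaneous_intervals_cover_point_estimates(self, strong_fit):
        _, contrasts = strong_fit
        assert (contrasts["lo"] <= contrasts["ratio"]).all()
        assert (contrasts["ratio"] <= contrasts["hi"]).all()
        assert contrasts.attrs["critical_value"] > 1.96  # wider than unadjusted

    def test_classification_recovers_planted_patterns(self, strong_fit):
        fit, contrasts = strong_fit
        labels = infl.classify_specialists(fit.cell_means, contrasts)
        assert labels["LitterFam"] == "litter"
        assert labels["FireFam"] == "fire"
        assert labels["NullFam"] == "none"

    def test_rule_application_on_stated_means(self):
        cells = list(sim.CELLS)
        means = pd.DataFrame(
            [[1.8, 1.6, 0.4, 0.5], [1.7, 0.6, 1.5, 0.7], [1.0, 1.0, 1.0, 1.0]],
            index=["lit", "fire", "null"],
            columns=cells,
        )
        rows = []
        for f in means.index:
            for i in range(4):
                for j in range(i + 1, 4):
                    rows.append(
                        {"family": f, "contrast": f"{cells[i]} / {cells[j]}",
                         "significant": f != "null"}
                    )
        contrasts = pd.DataFrame(rows)
        labels = infl.classify_specialists(means, contrasts)
        assert labels.tolist() == ["litter", "fire", "none"]

    def test_substrate_relabel_swaps_labels(self):
        cells = list(sim.CELLS)
        means = pd.DataFrame([[1.8, 1.6, 0.4, 0.5]], index=["f"], columns=cells)
        swapped = means.rename(
            columns={"burnt-litter": "burnt-soil", "burnt-soil": "burnt-litter",
                     "unburnt-litter": "unburnt-soil", "unburnt-soil": "unburnt-litter"}
        )
        rows = [
            {"family": "f", "contrast": f"{cells[i]} / {cells[j]}", "significant": True}
            for i in range(4)
            for j in range(i + 1, 4)
        ]
        contrasts = pd.DataFrame(rows)
        assert infl.classify_specialists(means, contrasts)["f"] == "litter"
        assert infl.classify_specialists(swapped, contrasts)["f"] == "soil"
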