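import numpy as np
import pandas as pd
import pytest
from scipy.linalg import hadamard

from mgidi import (
    MGIDI,
    IdeotypeSpec,
    MeansTable,
    SimConfig,
    compute_mgidi,
    ideal_scores,
    planted_best_scenario,
    rank_and_select,
    rescale_table,
    fit_factor_model,
    run_pipeline,
    selection_differentials,
    strengths_weaknesses,
)
from tests.conftest import random_means


class TestComputeMgidi:
    def test_score_at_ideal_gives_zero(self):
        gamma = np.array([1.0, -2.0])
        d = compute_mgidi(np.array([[1.0, -2.0]]), gamma)
        assert d[0] == 0.0

    def test_three_four_five(self):
        d = compute_mgidi(np.array([[3.0, 4.0], [1.0, 0.0]]), np.zeros(2))
        np.testing.assert_allclose(d, [5.0, 1.0])

    def test_matches_brute_force_sum_of_squares(self, rng):
        F = rng.standard_normal((6, 3))
        gamma = rng.standard_normal(3)
        expected = [
            np.sqrt(sum((F[i, j] - gamma[j]) ** 2 for j in range(3)))
            for i in range(6)
        ]
        np.testing.assert_allclose(compute_mgidi(F, gamma), expected, atol=1e-12)


class TestStrengthsWeaknesses:
    def test_single_factor_share_is_one(self, rng):
        F = rng.standard_normal((4, 1))
        omega, _, _ = strengths_weaknesses(F, np.zeros(1))
        np.testing.assert_allclose(omega, 1.0)

    def test_direct_ratio(self):
        omega, D, _ = strengths_weaknesses(
            np.array([[3.0, -1.0]]), np.zeros(2)
        )
        np.testing.assert_allclose(D, [[3.0, 1.0]])
        np.testing.assert_allclose(omega, [[0.75, 0.25]])

    def test_rows_sum_to_one(self, rng):
        F = rng.standard_normal((8, 4))
        omega, _, at_ideal = strengths_weaknesses(F, rng.standard_normal(4))
        np.testing.assert_allclose(omega.sum(axis=1), 1.0, atol=1e-9)
        assert not at_ideal.any()

    def test_treatment_at_ideal_flagged_uniform(self):
        gamma = np.array([0.5, 1.5])
        F = np.array([[0.5, 1.5], [1.0, 0.0]])
        omega, _, at_ideal = strengths_weaknesses(F, gamma)
        assert at_ideal.tolist() == [True, False]
        np.testing.assert_allclose(omega[0], [0.5, 0.5])


class TestSelectionDifferentials:
    def _means(self):
        return MeansTable(
            pd.DataFrame(
                {"Y": [10.0, 20.0, 30.0, 40.0], "W": [4.0, 3.0, 2.0, 1.0]},
                index=["T1", "T2", "T3", "T4"],
            )
        )

    def test_selecting_everything_gives_zero(self):
        spec = IdeotypeSpec.uniform(["Y", "W"])
        sd = selection_differentials(self._means(), ["T1", "T2", "T3", "T4"], spec)
        np.testing.assert_allclose(sd["sd_percent"], 0.0)
        assert sd["desired"].all()  # zero movement counts as desired

    def test_top_two_higher_is_plus_forty_percent(self):
        spec = IdeotypeSpec.uniform(["Y", "W"])
        sd = selection_differentials(self._means(), ["T3", "T4"], spec)
        assert sd.loc["Y", "sd_percent"] == pytest.approx(40.0)  # (35-25)/25
        assert bool(sd.loc["Y", "desired"])
        # W fell from 2.5 to 1.5 => -40%, undesired for "higher"
        assert sd.loc["W", "sd_percent"] == pytest.approx(-40.0)
        assert not bool(sd.loc["W", "desired"])

    def test_lower_direction_flips_desired_flag(self):
        spec = IdeotypeSpec.from_directions({"Y": "lower", "W": "lower"})
        sd = selection_differentials(self._means(), ["T3", "T4"], spec)
        assert not bool(sd.loc["Y", "desired"])
        assert bool(sd.loc["W", "desired"])

    def test_zero_overall_mean_reports_absolute_difference(self):
        means = MeansTable(
            pd.DataFrame(
                {"Y": [-1.0, 1.0, -2.0, 2.0], "W": [1.0, 2.0, 3.0, 4.0]},
                index=["T1", "T2", "T3", "T4"],
            )
        )
        spec = IdeotypeSpec.uniform(["Y", "W"])
        sd = selection_differentials(means, ["T2", "T4"], spec)
        assert not bool(sd.loc["Y", "relative"])
        assert sd.loc["Y", "sd_percent"] == pytest.approx(1.5)  # absolute diff

    def test_unknown_treatment_rejected(self):
        with pytest.raises(KeyError, match="T9"):
            selection_differentials(
                self._means(), ["T9"], IdeotypeSpec.uniform(["Y", "W"])
            )


class TestRankAndSelect:
    def test_ascending_distance_ranks(self):
        ranks, sel = rank_and_select(np.array([0.5, 0.1, 0.9]), k=1)
        assert ranks.tolist() == [2, 1, 3]
        assert sel.tolist() == [False, True, False]

    def test_tie_at_boundary_warns_and_keeps_input_order(self):
        with pytest.warns(RuntimeWarning, match="tie"):
            ranks, sel = rank_and_select(np.array([0.3, 0.3, 0.9]), k=1)
        assert sel.tolist() == [True, False, False]
        assert ranks.tolist() == [1, 2, 3]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="k must be"):
            rank_and_select(np.array([1.0, 2.0]), k=3)

    def test_ranks_are_a_permutation(self, rng):
        d = rng.standard_normal(9) ** 2
        ranks, _ = rank_and_select(d, k=4)
        assert sorted(ranks.tolist()) == list(range(1, 10))


class TestIdealScores:
    def test_treatment_attaining_ideal_has_gamma_scores(self, rng):
        # treatment T1 dominates every trait => rescaled row of all 100s
        arr = rng.uniform(10, 50, (5, 4))
        arr[0] = 99.0
        means = MeansTable(
            pd.DataFrame(arr, index=[f"T{i+1}" for i in range(5)],
                         columns=[f"V{j+1}" for j in range(4)])
        )
        spec = IdeotypeSpec.uniform(means.traits)
        res = MGIDI(means, spec).fit(k=1)
        np.testing.assert_allclose(
            res.factor_model.scores.loc["T1"].to_numpy(), res.gamma, atol=1e-8
        )
        assert res.distances["T1"] == pytest.approx(0.0, abs=1e-8)
        assert bool(res.at_ideal["T1"])

    def test_doubling_all_weights_doubles_gamma(self, rng):
        means = random_means(rng, 6, 4)
        spec = IdeotypeSpec.uniform(means.traits)
        rescaled = rescale_table(means, spec)
        model = fit_factor_model(rescaled)
        g1 = ideal_scores(model, spec, rescaled)
        spec2 = spec.with_weights({t: 2.0 for t in means.traits})
        g2 = ideal_scores(model, spec2, rescaled)
        np.testing.assert_allclose(g2, 2.0 * g1, atol=1e-10)

    def test_upweighted_trait_inflates_its_factor(self, rng):
        # two independent trait blocks; weighting a block-1 trait must
        # inflate |gamma| of the factor holding that block
        n = 30
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "A0": 10 * f1 + 0.2 * rng.standard_normal(n) + 50,
                "A1": 9 * f1 + 0.2 * rng.standard_normal(n) + 40,
                "B0": 10 * f2 + 0.2 * rng.standard_normal(n) + 50,
                "B1": 9 * f2 + 0.2 * rng.standard_normal(n) + 40,
            },
            index=[f"T{i}" for i in range(n)],
        )
        means = MeansTable(df)
        spec = IdeotypeSpec.uniform(means.traits)
        rescaled = rescale_table(means, spec)
        model = fit_factor_model(rescaled)
        assert model.n_factors == 2
        fa_of_A = model.trait_assignment["A0"]
        j = model.factor_names.index(fa_of_A)
        g1 = ideal_scores(model, spec, rescaled)
        g4 = ideal_scores(
            model, spec.with_weights({"A0": 4.0, "A1": 4.0}), rescaled
        )
        assert abs(g4[j]) > abs(g1[j])

    def test_factor_weight_mode_scales_scores_directly(self, rng):
        means = random_means(rng, 6, 4)
        spec = IdeotypeSpec.uniform(means.traits)
        rescaled = rescale_table(means, spec)
        model = fit_factor_model(rescaled)
        base = ideal_scores(model, spec, rescaled, weight_mode="factor")
        fw = np.arange(1.0, model.n_factors + 1)
        scaled = ideal_scores(
            model, spec, rescaled, weight_mode="factor", factor_weights=fw
        )
        np.testing.assert_allclose(scaled, base * fw, atol=1e-12)


class TestPipeline:
    @pytest.mark.parametrize(
        "directions",
        [
            ["higher"] * 3,
            ["lower", "lower", "higher"],
            ["lower"] * 3,
        ],
        ids=["all-higher", "mixed", "all-lower"],
    )
    def test_planted_ideal_ranks_first_under_each_regime(self, directions):
        cfg = SimConfig(n_treatments=5, n_blocks=3, n_traits=3, seed=17)
        table = planted_best_scenario(cfg, 1, directions, effect_size=8.0)
        spec = IdeotypeSpec.from_directions(
            dict(zip(["V1", "V2", "V3"], directions))
        )
        res = run_pipeline(table, spec, term=["TRT"], k=1)
        assert res.selected == ["T2"]
        assert res.ranks["T2"] == 1

    def test_all_one_weights_identical_to_unweighted(self, rng):
        means = random_means(rng, 6, 5)
        spec = IdeotypeSpec.uniform(means.traits)
        res_a = MGIDI(means, spec).fit(k=2)
        res_b = MGIDI(
            means, spec.with_weights({t: 1.0 for t in means.traits})
        ).fit(k=2)
        assert (res_a.distances == res_b.distances).all()
        assert res_a.selected == res_b.selected

    def test_invariant_to_factor_sign_flips(self, rng):
        # distances are computed in a coordinate system defined up to
        # column sign; flipping score + gamma signs must not change them
        means = random_means(rng, 7, 5)
        spec = IdeotypeSpec.uniform(means.traits)
        res = MGIDI(means, spec).fit(k=2)
        F = res.factor_model.scores.to_numpy()
        gamma = res.gamma
        flip = np.array([(-1.0) ** j for j in range(F.shape[1])])
        d_flipped = compute_mgidi(F * flip, gamma * flip)
        np.testing.assert_allclose(d_flipped, res.distances.to_numpy(), atol=1e-10)

    def test_orthogonal_table_reduces_to_euclidean_ranking(self):
        # Hadamard columns give an exactly identity sample correlation,
        # so with all factors retained the index must reproduce the
        # Euclidean distance ranking on standardized rescaled traits
        H = hadamard(8).astype(float)
        df = pd.DataFrame(
            50.0 + 40.0 * H[:, 1:5],
            index=[f"T{i}" for i in range(8)],
            columns=list("abcd"),
        )
        # break ties so the ranking is unique
        df += np.arange(8)[:, None] * 0.5
        means = MeansTable(df)
        spec = IdeotypeSpec.uniform(means.traits)
        res = MGIDI(means, spec, n_factors=4).fit(k=2)
        rescaled = rescale_table(means, spec).values
        z = (rescaled - rescaled.mean()) / rescaled.std(ddof=1)
        z_ideal = (100.0 - rescaled.mean()) / rescaled.std(ddof=1)
        brute = np.sqrt(((z - z_ideal) ** 2).sum(axis=1))
        np.testing.assert_allclose(
            res.distances.rank().to_numpy(), brute.rank().to_numpy()
        )

    def test_duplicated_trait_matches_univariate_ranking(self, rng):
        # p = 2 via a duplicated (noisily jittered) trait: the MGIDI
        # order must match the direction-adjusted univariate order
        y = rng.uniform(0, 100, 6)
        df = pd.DataFrame(
            {"Y": y, "Y2": y + 1e-9 * rng.standard_normal(6)},
            index=[f"T{i}" for i in range(6)],
        )
        means = MeansTable(df)
        spec = IdeotypeSpec.from_directions({"Y": "lower", "Y2": "lower"})
        res = MGIDI(means, spec).fit(k=1)
        best = df["Y"].idxmin()
        assert res.ranks[best] == 1
        order = res.distances.sort_values().index.tolist()
        assert order == df["Y"].sort_values().index.tolist()

    def test_upweighting_does_not_rescue_worst_treatment(self):
        # separable fixture: factor-1 traits vary only between rows; the
        # treatment worst in factor 1 cannot improve when a factor-1
        # trait is upweighted
        gen = np.random.default_rng(99)
        arr = gen.uniform(20, 80, (6, 4))
        arr[5, 0] = 1.0  # T6 is worst in trait a (factor 1 block)
        arr[5, 1] = 1.0
        df = pd.DataFrame(
            arr, index=[f"T{i+1}" for i in range(6)], columns=list("abcd")
        )
        means = MeansTable(df)
        spec = IdeotypeSpec.uniform(means.traits)
        r0 = MGIDI(means, spec).fit(k=2).ranks["T6"]
        r1 = MGIDI(means, spec.with_weights({"a": 5.0})).fit(k=2).ranks["T6"]
        assert r1 >= r0

    def test_results_summary_shape(self, rng):
        means = random_means(rng, 5, 4)
        res = MGIDI(means, IdeotypeSpec.uniform(means.traits)).fit()
        s = res.summary()
        assert list(s.columns) == ["MGIDI", "rank", "selected"]
        assert len(s) == 5
        assert s["selected"].sum() == 3  # default k = ceil(5/2)
        assert sorted(s["rank"]) == [1, 2, 3, 4, 5]
        assert res.differentials.shape[0] == 4
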